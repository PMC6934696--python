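"""Circuit right-hand side, Jacobian and energy-scaling functions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from energytoggle import (
    EnergyModel,
    LINEAR,
    RegulatoryParams,
    SIGMOID,
    apply_override,
    jacobian,
    lambda_energy,
    map_atp_to_astar,
    production_bound,
    rhs,
)
from energytoggle.scenarios import random_params

SHIFTED = EnergyModel(kind="shifted", floor=0.1, ceiling=1.2)


class TestLambdaEnergy:
    @pytest.mark.parametrize("a_star, model, expected", [
        (0.5, SIGMOID, 0.5),                        # sigmoid midpoint: exponent 0
        (1.0, SIGMOID, 1.0 / (1.0 + math.exp(-8.0))),
        (0.0, SIGMOID, 1.0 / (1.0 + math.exp(8.0))),
        (0.3, LINEAR, 0.3),
        (0.5, SHIFTED, 0.1 + 1.1 * 0.5),            # affine rescale of the midpoint
    ])
    def test_point_values(self, a_star, model, expected):
        assert lambda_energy(a_star, model) == pytest.approx(expected, rel=1e-12)

    def test_sigmoid_midpoint_exact(self):
        assert lambda_energy(0.5, SIGMOID) == 0.5

    @pytest.mark.parametrize("model", [SIGMOID, LINEAR, SHIFTED])
    def test_strictly_increasing_on_unit_interval(self, model):
        grid = np.linspace(0.0, 1.0, 1001)
        vals = lambda_energy(grid, model)
        assert np.all(np.diff(vals) > 0)

    def test_sigmoid_defaults_bounded_in_open_unit_interval(self):
        grid = np.linspace(0.0, 1.0, 101)
        vals = lambda_energy(grid, SIGMOID)
        assert np.all((vals > 0) & (vals < 1))

    def test_shifted_nonzero_at_zero_and_exceeds_one(self):
        assert lambda_energy(0.0, SHIFTED) > 0
        assert lambda_energy(1.0, SHIFTED) > 1

    def test_warns_outside_unit_interval_for_sigmoid_and_linear(self):
        for model in (SIGMOID, LINEAR):
            with pytest.warns(UserWarning):
                lambda_energy(1.5, model)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            EnergyModel(kind="shifted", floor=-0.1)
        with pytest.raises(ValueError):
            EnergyModel(kind="shifted", floor=1.0, ceiling=0.5)
        with pytest.raises(ValueError):
            EnergyModel(kind="exponential")


class TestRegulatoryParams:
    def test_defaults_factory(self):
        p = RegulatoryParams.defaults()
        assert (p.a1, p.a2, p.b1, p.b2, p.k1, p.k2) == (1,) * 6
        assert (p.theta_a1, p.theta_a2, p.theta_b1, p.theta_b2) == (0.5,) * 4
        assert p.n == 4

    def test_dict_round_trip(self):
        p = RegulatoryParams.defaults()
        assert RegulatoryParams.from_dict(p.to_dict()) == p

    @pytest.mark.parametrize("kwargs", [
        {"k1": 0.0}, {"a2": -1.0}, {"theta_b1": 0.0}, {"n": 0.5}, {"b1": -0.1},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RegulatoryParams(**kwargs)

    def test_apply_override_symmetric_and_individual(self):
        p = apply_override(RegulatoryParams.defaults(), "b", 2.0)
        assert p.b1 == p.b2 == 2.0
        q = apply_override(p, "a1", 3.0)
        assert (q.a1, q.a2) == (3.0, 1.0)
        with pytest.raises(ValueError):
            apply_override(p, "gamma", 1.0)


class TestRhs:
    def test_origin_production_only(self, defaults):
        # at (0,0) activation vanishes and repression is maximal (= b)
        np.testing.assert_allclose(rhs((0.0, 0.0), defaults, 1.0), [1.0, 1.0])

    def test_zero_energy_pure_decay(self, defaults):
        x = np.array([0.7, 1.3])
        np.testing.assert_allclose(rhs(x, defaults, 0.0), -x)

    def test_half_point_hand_value(self, defaults):
        # both Hill terms are exactly 1/2 at x = theta = 0.5
        np.testing.assert_allclose(rhs((0.5, 0.5), defaults, 1.0), [0.5, 0.5])

    @pytest.mark.parametrize("bad", [(-0.1, 0.5), (np.nan, 0.5), (np.inf, 1.0)])
    def test_rejects_invalid_state(self, defaults, bad):
        with pytest.raises(ValueError):
            rhs(bad, defaults, 1.0)

    def test_rejects_negative_lam(self, defaults):
        with pytest.raises(ValueError):
            rhs((0.5, 0.5), defaults, -0.2)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(x1=st.floats(0.0, 3.0), x2=st.floats(0.0, 3.0), seed=st.integers(0, 100),
           lam=st.floats(0.0, 1.2))
    def test_index_swap_symmetry(self, x1, x2, seed, lam):
        """Swapping (x1,x2) together with the gene-1/gene-2 constants swaps the output."""
        p = random_params(seed=seed, symmetric=False)
        swapped = RegulatoryParams(a1=p.a2, a2=p.a1, b1=p.b2, b2=p.b1, k1=p.k2,
                                   k2=p.k1, theta_a1=p.theta_a2, theta_a2=p.theta_a1,
                                   theta_b1=p.theta_b2, theta_b2=p.theta_b1, n=p.n)
        d = rhs((x1, x2), p, lam)
        d_sw = rhs((x2, x1), swapped, lam)
        np.testing.assert_allclose(d, d_sw[::-1], rtol=1e-12, atol=0)

    def test_forward_invariance_on_axes(self, rng):
        """The flow never exits the non-negative quadrant: dx_i >= 0 at x_i = 0."""
        for _ in range(50):
            p = random_params(rng=rng)
            lam = rng.uniform(0.0, 1.0)
            other = rng.uniform(0.0, 3.0)
            assert rhs((0.0, other), p, lam)[0] >= 0
            assert rhs((other, 0.0), p, lam)[1] >= 0


class TestJacobian:
    def test_zero_energy_is_pure_degradation(self, defaults):
        J = jacobian((0.8, 0.2), defaults, 0.0)
        np.testing.assert_allclose(J, np.diag([-1.0, -1.0]))

    def test_symmetric_point_symmetric_entries(self, defaults):
        J = jacobian((0.7, 0.7), defaults, 0.9)
        assert J[0, 0] == pytest.approx(J[1, 1])
        assert J[0, 1] == pytest.approx(J[1, 0])

    def test_off_diagonal_nonpositive(self, rng):
        for _ in range(20):
            p = random_params(rng=rng, symmetric=False)
            x = rng.uniform(0.0, 3.0, size=2)
            J = jacobian(x, p, rng.uniform(0.0, 1.0))
            assert J[0, 1] <= 0 and J[1, 0] <= 0

    def test_matches_finite_differences(self):
        """Analytic Jacobian vs central differences on 100 seeded draws."""
        rng = np.random.default_rng(42)
        h = 1e-6
        for _ in range(100):
            p = random_params(rng=rng, symmetric=False)
            lam = rng.uniform(0.05, 1.0)
            x = rng.uniform(0.05, 2.5, size=2)
            J = jacobian(x, p, lam)
            fd = np.empty((2, 2))
            for j in range(2):
                e = np.zeros(2)
                e[j] = h
                fd[:, j] = (rhs(x + e, p, lam) - rhs(x - e, p, lam)) / (2 * h)
            np.testing.assert_allclose(J, fd, rtol=1e-6, atol=1e-8)

    def test_hill_derivative_limit_at_zero(self):
        # n>1: activation derivative vanishes at 0; n=1: it equals a/theta_a
        p4 = RegulatoryParams.defaults()
        assert jacobian((0.0, 1.0), p4, 1.0)[0, 0] == pytest.approx(-p4.k1)
        p1 = RegulatoryParams.symmetric(n=1)
        expected = 1.0 * p1.a1 / p1.theta_a1 - p1.k1
        assert jacobian((0.0, 1.0), p1, 1.0)[0, 0] == pytest.approx(expected)

    def test_rejects_non_finite_state(self, defaults):
        with pytest.raises(ValueError):
            jacobian((np.nan, 0.5), defaults, 1.0)


class TestAtpMapping:
    def test_bounds_and_midpoint(self):
        lo = map_atp_to_astar(320.0)
        assert float(lo) == pytest.approx(0.0)
        assert lo.sub_critical
        hi = map_atp_to_astar(2760.0)
        assert float(hi) == pytest.approx(1.0)
        assert not hi.sub_critical
        assert float(map_atp_to_astar(1540.0)) == pytest.approx(0.5)

    def test_below_lower_bound_flags_sub_critical(self):
        lvl = map_atp_to_astar(200.0)
        assert float(lvl) < 0 and lvl.sub_critical

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            map_atp_to_astar(-5.0)
        with pytest.raises(ValueError):
            map_atp_to_astar(500.0, lo=1000.0, hi=100.0)


def test_production_bound_caps_rhs_growth(defaults):
    # beyond x_max both derivatives are negative: the box is absorbing
    xm = production_bound(defaults, 1.0)
    d = rhs((xm * 1.01, xm * 1.01), defaults, 1.0)
    assert np.all(d < 0)
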