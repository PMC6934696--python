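"""Multistart root finding, deduplication and stability classification."""

import numpy as np
import pytest
import scipy.optimize

from energytoggle import (
    RegulatoryParams,
    attractor_of,
    classify_stability,
    deduplicate_roots,
    find_steady_states,
    integrate_to_rest,
    lambda_energy,
    production_bound,
    rhs,
)
from energytoggle.scenarios import random_params


class TestFindSteadyStates:
    def test_default_circuit_is_tristable(self, tristable):
        assert tristable.n_stable == 3
        assert len(tristable.steady_states) >= 5  # 3 sinks + 2 saddles

    def test_noncooperative_binding_is_monostable(self):
        att = find_steady_states(RegulatoryParams.symmetric(n=1), 1.0)
        assert att.n_stable == 1

    def test_zero_energy_single_attractor_near_origin(self, defaults):
        att = find_steady_states(defaults, 0.0)
        assert att.n_stable == 1
        bound = production_bound(defaults, lambda_energy(0.0))
        pt = att.stable_points()[0]
        assert np.all(pt <= bound + 1e-5)

    def test_roots_verified_and_nonnegative(self, tristable):
        for s in tristable.steady_states:
            assert s.residual < 1e-9
            assert s.x1 >= 0 and s.x2 >= 0

    def test_rejects_too_coarse_start_grid(self, defaults):
        with pytest.raises(ValueError):
            find_steady_states(defaults, 1.0, grid=10)

    def test_roots_confirmed_by_levenberg_marquardt(self, tristable):
        """Independent cross-check: scipy's LM solver reproduces every root."""
        p, lam = tristable.params, tristable.lam
        for s in tristable.steady_states:
            x0 = s.state + 1e-3
            sol = scipy.optimize.root(lambda x: rhs(np.clip(x, 0, None), p, lam),
                                      x0, method="lm", tol=1e-12)
            assert sol.success
            assert np.linalg.norm(sol.x - s.state) < 1e-6

    def test_symmetry_closure_and_boundedness_on_random_draws(self, rng):
        for _ in range(10):
            p = random_params(rng=rng)  # symmetric draws
            a_star = rng.uniform(0.0, 1.0)
            att = find_steady_states(p, a_star)
            pts = np.array([s.state for s in att.steady_states])
            # mirror closure: the set is invariant under (x1,x2) -> (x2,x1)
            for q in pts:
                assert np.min(np.linalg.norm(pts - q[::-1], axis=1)) < 1e-5
            bound = production_bound(p, att.lam)
            assert np.all(pts <= bound + 1e-5)
            assert att.n_stable >= 1

    def test_serializes_to_long_table(self, tristable):
        frame = tristable.to_frame()
        assert list(frame.columns) == ["a_star", "x1", "x2", "stability",
                                       "leading_re", "residual"]
        assert (frame.stability == "stable").sum() == 3


class TestClassifyStability:
    def test_origin_stable_at_zero_energy(self, defaults):
        label, leading = classify_stability((0.0, 0.0), defaults, 0.0)
        assert label == "stable"
        assert leading == pytest.approx(-1.0)  # eigenvalues -k1, -k2

    def test_intermediate_attractor_is_stable(self, tristable):
        sym = [s for s in tristable.stable if abs(s.x1 - s.x2) < 1e-6]
        assert len(sym) == 1 and sym[0].stability == "stable"

    def test_rejects_non_root(self, defaults):
        with pytest.raises(ValueError):
            classify_stability((0.3, 0.3), defaults, 1.0)


class TestDeduplicateRoots:
    def test_merges_nearby_keeps_distant(self):
        merged = deduplicate_roots([(1.0, 0.0), (1.0 + 1e-8, 0.0)], 1e-5)
        assert len(merged) == 1
        kept = deduplicate_roots([(1.0, 0.0), (0.0, 1.0)], 1e-5)
        assert len(kept) == 2

    def test_representative_has_smallest_residual(self):
        roots = [(1.0 + 1e-7, 0.0), (1.0, 0.0)]
        reps = deduplicate_roots(roots, 1e-5, residuals=[1e-6, 1e-12])
        assert reps[0][0] == 1.0

    def test_output_pairwise_separated(self, rng):
        roots = rng.uniform(0, 1, size=(50, 2))
        reps = deduplicate_roots(roots, 0.1)
        for i, p in enumerate(reps):
            for q in reps[i + 1:]:
                assert np.linalg.norm(p - q) > 0.1

    def test_rejects_nonpositive_tolerance(self):
        with pytest.raises(ValueError):
            deduplicate_roots([(1.0, 0.0)], 0.0)


class TestAttractorOf:
    def test_attractor_maps_to_itself(self, tristable):
        for i, s in enumerate(tristable.stable):
            assert attractor_of(s.state, tristable) == i

    def test_biased_start_reaches_matching_extreme(self, tristable):
        pts = tristable.stable_points()
        hi_x1 = int(np.argmax(pts[:, 0] - pts[:, 1]))
        hi_x2 = int(np.argmax(pts[:, 1] - pts[:, 0]))
        assert attractor_of((2.0, 0.0), tristable) == hi_x1
        assert attractor_of((0.0, 2.0), tristable) == hi_x2

    def test_mirrored_starts_reach_mirrored_attractors(self, tristable):
        pts = tristable.stable_points()
        i = attractor_of((1.7, 0.4), tristable)
        j = attractor_of((0.4, 1.7), tristable)
        np.testing.assert_allclose(pts[i], pts[j][::-1], atol=1e-6)

    def test_nonconvergent_raises(self, tristable):
        with pytest.raises(RuntimeError):
            attractor_of((2.0, 0.0), tristable, t_max=0.01)


def test_stable_roots_equal_trajectory_limits_on_random_circuits():
    """Oracle equivalence on 20 seeded random circuits.

    The stable roots reported by Newton multistart must coincide with the
    distinct limits of trajectories launched from a dense 21x21 grid of
    initial conditions: every stable root is reached, and every limit
    matches a root.  Exactly symmetric starts (the grid diagonal of a
    symmetric circuit) lie on the stable manifold of the diagonal saddle
    and legitimately converge to an unstable root; those limits must match
    a known unstable root and nothing else.
    """
    rng = np.random.default_rng(7)
    for _ in range(20):
        p = random_params(rng=rng)
        a_star = rng.uniform(0.2, 1.0)
        att = find_steady_states(p, a_star)
        stable_pts = att.stable_points()
        all_pts = np.array([s.state for s in att.steady_states])
        span = 1.2 * max(production_bound(p, att.lam), 1e-2)
        g = np.linspace(0, span, 21)
        xx, yy = np.meshgrid(g, g)
        starts = np.column_stack([xx.ravel(), yy.ravel()])
        term, conv = integrate_to_rest(starts, p, att.lam, t_max=400.0, conv_tol=1e-8)
        assert conv.all()
        d_stable = np.linalg.norm(term[:, None, :] - stable_pts[None, :, :], axis=2)
        nearest = d_stable.min(axis=1)
        to_saddle = ~(nearest < 1e-3)
        if to_saddle.any():
            # only exact-diagonal starts may do this, and only onto a known root
            assert np.allclose(starts[to_saddle, 0], starts[to_saddle, 1])
            d_any = np.linalg.norm(term[to_saddle, None, :] - all_pts[None, :, :], axis=2)
            assert d_any.min(axis=1).max() < 1e-3, f"unmatched limit for params {p}"
        # every stable root is reached by at least one trajectory
        hit = set(np.argmin(d_stable, axis=1)[nearest < 1e-3])
        assert hit == set(range(len(stable_pts)))
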