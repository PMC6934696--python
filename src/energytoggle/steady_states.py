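"""Steady-state location and stability classification.

All steady states of the energy-scaled circuit are found by multistart
root finding: a damped Newton iteration (using the analytic Jacobian) is
run in parallel from a grid of initial guesses covering the invariant box
[0, margin * x_max]^2, where x_max = max_i lam*(a_i+b_i)/k_i bounds every
steady state.  Converged roots are verified, deduplicated and classified
by the real parts of the Jacobian eigenvalues.  Marginal roots (leading
real part within ``stability_eps`` of zero) are labelled unstable — they
are functionally unstable: expression noise will not hold the system
there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    SIGMOID,
    EnergyModel,
    RegulatoryParams,
    _as_xy,
    _jacobian_xy,
    _rhs_xy,
    lambda_energy,
    production_bound,
)

__all__ = [
    "SteadyState",
    "AttractorSet",
    "find_steady_states",
    "classify_stability",
    "deduplicate_roots",
    "attractor_of",
    "integrate_to_rest",
]

#: default numerical tolerances, shared by the higher-level analyses
RESIDUAL_TOL = 1e-9
DEDUP_TOL = 1e-5
STABILITY_EPS = 1e-8
CONV_TOL = 1e-8
MATCH_TOL = 1e-3
T_MAX = 500.0


@dataclass(frozen=True)
class SteadyState:
    """A verified root of the system with its stability label.

    ``leading_re`` is the largest real part among the two Jacobian
    eigenvalues (units 1/time); ``residual`` the Euclidean norm of the
    vector field at the root.
    """

    x1: float
    x2: float
    stability: str            # "stable" | "unstable"
    leading_re: float
    residual: float

    @property
    def state(self) -> np.ndarray:
        return np.array([self.x1, self.x2])

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass
class AttractorSet:
    """All distinct steady states at one (parameter set, energy) point."""

    steady_states: list[SteadyState]
    params: RegulatoryParams
    a_star: float
    model: EnergyModel = SIGMOID

    @property
    def lam(self) -> float:
        return float(lambda_energy(self.a_star, self.model))

    @property
    def stable(self) -> list[SteadyState]:
        return [s for s in self.steady_states if s.is_stable]

    @property
    def n_stable(self) -> int:
        return len(self.stable)

    def stable_points(self) -> np.ndarray:
        """Stable attractor coordinates, shape (n_stable, 2)."""
        pts = [s.state for s in self.stable]
        return np.array(pts) if pts else np.empty((0, 2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"a_star": self.a_star,
             "x1": [s.x1 for s in self.steady_states],
             "x2": [s.x2 for s in self.steady_states],
             "stability": [s.stability for s in self.steady_states],
             "leading_re": [s.leading_re for s in self.steady_states],
             "residual": [s.residual for s in self.steady_states]})


def _leading_real_eig(j11, j12, j21, j22):
    """Largest real part of the eigenvalues of [[j11,j12],[j21,j22]]."""
    tr = j11 + j22
    det = j11 * j22 - j12 * j21
    disc = tr * tr - 4.0 * det
    real_pair = disc >= 0
    root = np.sqrt(np.where(real_pair, disc, 0.0))
    return np.where(real_pair, 0.5 * (tr + root), 0.5 * tr)


def _residual_norm(x, params, lam):
    d1, d2 = _rhs_xy(x[..., 0], x[..., 1], params, lam)
    return np.hypot(d1, d2)


def _newton_multistart(starts: np.ndarray, params: RegulatoryParams, lam: float,
                       span: float, tol: float, max_iter: int = 200) -> np.ndarray:
    """Damped Newton from every row of ``starts``; returns converged points.

    Iterates are projected onto the non-negative quadrant; steps are capped
    at half the search span.  Starts whose Jacobian becomes singular simply
    fail to converge and are dropped — the grid provides ample redundancy.
    """
    x = starts.astype(float).copy()
    cap = 0.5 * span + 1e-3
    active = np.ones(len(x), dtype=bool)
    for _ in range(max_iter):
        xa = x[active]
        if xa.size == 0:
            break
        f1, f2 = _rhs_xy(xa[:, 0], xa[:, 1], params, lam)
        done = np.hypot(f1, f2) < tol
        if done.all():
            idx = np.flatnonzero(active)
            active[idx] = False
            break
        j11, j12, j21, j22 = _jacobian_xy(xa[:, 0], xa[:, 1], params, lam)
        det = j11 * j22 - j12 * j21
        ok = np.abs(det) > 1e-300
        inv_det = np.where(ok, det, 1.0)
        d1 = -(j22 * f1 - j12 * f2) / inv_det
        d2 = -(-j21 * f1 + j11 * f2) / inv_det
        d1 = np.where(ok, d1, 0.0)
        d2 = np.where(ok, d2, 0.0)
        step = np.hypot(d1, d2)
        scale = np.where(step > cap, cap / np.maximum(step, 1e-300), 1.0)
        xa[:, 0] = np.clip(xa[:, 0] + scale * d1, 0.0, None)
        xa[:, 1] = np.clip(xa[:, 1] + scale * d2, 0.0, None)
        # freeze already-converged starts so later steps cannot unsettle them
        idx = np.flatnonzero(active)
        x[idx[~done]] = xa[~done]
        active[idx[done]] = False
    res = _residual_norm(x, params, lam)
    good = np.isfinite(res) & (res < tol) & np.all(np.isfinite(x), axis=1) & np.all(x >= 0, axis=1)
    return x[good]


def deduplicate_roots(roots, dedup_tol: float = DEDUP_TOL, residuals=None):
    """Greedy Euclidean clustering of near-identical roots.

    Each cluster is represented by its member with the smallest residual
    (first member if residuals are not supplied); representatives are
    pairwise separated by more than ``dedup_tol``.
    """
    if dedup_tol <= 0:
        raise ValueError("dedup_tol must be positive")
    pts = np.asarray([_as_xy(r) for r in roots], dtype=float)
    if pts.size == 0:
        return []
    res = (np.asarray(residuals, dtype=float) if residuals is not None
           else np.arange(len(pts), dtype=float))
    order = np.argsort(res, kind="stable")  # best residual claims its cluster
    reps: list[np.ndarray] = []
    for i in order:
        p = pts[i]
        if all(np.linalg.norm(p - q) > dedup_tol for q in reps):
            reps.append(p)
    reps.sort(key=lambda p: (p[0], p[1]))
    return [np.array(p) for p in reps]


def classify_stability(state, params: RegulatoryParams, lam: float,
                       eps: float = STABILITY_EPS,
                       residual_tol: float = RESIDUAL_TOL):
    """Label a verified root stable/unstable from the Jacobian eigenvalues.

    Returns ``(label, leading_re)``.  Stable means every eigenvalue real
    part is below ``-eps``; marginal roots count as unstable.  Raises if
    ``state`` is not a root to within ``residual_tol``.
    """
    x = _as_xy(state)
    res = float(_residual_norm(x, params, lam))
    if not res < residual_tol:
        raise ValueError(f"state is not a steady state (residual {res:.3e} >= {residual_tol:.1e})")
    j11, j12, j21, j22 = _jacobian_xy(x[0], x[1], params, lam)
    leading = float(_leading_real_eig(j11, j12, j21, j22))
    label = "stable" if leading < -eps else "unstable"
    return label, leading


def find_steady_states(params: RegulatoryParams, a_star, model: EnergyModel = SIGMOID,
                       grid: int = 25, margin: float = 1.2,
                       residual_tol: float = RESIDUAL_TOL,
                       dedup_tol: float = DEDUP_TOL,
                       stability_eps: float = STABILITY_EPS) -> AttractorSet:
    """Locate every distinct steady state at one energy level.

    Newton is started from a ``grid`` x ``grid`` lattice of initial guesses
    covering [0, margin * x_max]^2.  Roots are verified (residual below
    ``residual_tol``, non-negative components), deduplicated and
    classified.  Raises RuntimeError if no root survives — a steady state
    always exists for positive rates, so that indicates numerical failure.
    """
    if grid < 15:
        raise ValueError("initial-guess grid must be at least 15x15")
    a_star = float(a_star)
    lam = float(lambda_energy(a_star, model))
    span = margin * max(production_bound(params, lam), 1e-2)
    g = np.linspace(0.0, span, grid)
    xx, yy = np.meshgrid(g, g)
    starts = np.column_stack([xx.ravel(), yy.ravel()])
    # iterate well below residual_tol: near-degenerate (quadratically flat)
    # regions would otherwise pass verification as a smear of false roots
    roots = _newton_multistart(starts, params, lam, span, min(residual_tol, 1e-13))
    reps = deduplicate_roots(roots, dedup_tol,
                             residuals=_residual_norm(roots, params, lam)) if len(roots) else []
    states = []
    for p in reps:
        label, leading = classify_stability(p, params, lam, eps=stability_eps,
                                            residual_tol=residual_tol)
        states.append(SteadyState(x1=float(p[0]), x2=float(p[1]), stability=label,
                                  leading_re=leading,
                                  residual=float(_residual_norm(p, params, lam))))
    if not states:
        raise RuntimeError(
            f"no steady state found (a_star={a_star}, params={params}); "
            "a root must exist — numerical failure")
    out = AttractorSet(steady_states=states, params=params, a_star=a_star, model=model)
    if lam > 0 and out.n_stable == 0:
        raise RuntimeError(
            f"no stable steady state at a_star={a_star} with lam={lam} > 0; "
            "all roots marginal/unstable — inspect tolerances")
    return out


def _time_step(params: RegulatoryParams, lam: float) -> float:
    """Fixed RK4 step from a crude Lipschitz bound on the vector field."""
    n, lam = params.n, max(lam, 0.0)
    slope = lam * max(params.a1 * n / params.theta_a1 + params.b2 * n / params.theta_b2,
                      params.a2 * n / params.theta_a2 + params.b1 * n / params.theta_b1)
    lip = max(params.k1, params.k2) + slope
    return float(np.clip(1.0 / lip, 1e-3, 0.05))


def integrate_to_rest(x0, params: RegulatoryParams, lam: float,
                      t_max: float = T_MAX, conv_tol: float = CONV_TOL,
                      dt: float | None = None, check_every: int = 20):
    """Integrate a batch of trajectories until the flow nearly vanishes.

    ``x0`` has shape (m, 2).  Classical RK4 with a fixed step chosen from a
    Lipschitz bound; every ``check_every`` steps trajectories with
    ||rhs|| < conv_tol are frozen.  Returns (terminal states, converged
    mask).  The non-negative quadrant is forward invariant; the clip only
    guards against tiny negative overshoot of the discrete steps.
    """
    x = np.atleast_2d(np.asarray(x0, dtype=float)).copy()
    if dt is None:
        dt = _time_step(params, lam)
    n_steps = int(np.ceil(t_max / dt))
    active = np.ones(len(x), dtype=bool)

    def f(pts):
        d1, d2 = _rhs_xy(pts[:, 0], pts[:, 1], params, lam)
        return np.column_stack([d1, d2])

    for step in range(n_steps):
        xa = x[active]
        if xa.size == 0:
            break
        k1 = f(xa)
        k2 = f(np.clip(xa + 0.5 * dt * k1, 0.0, None))
        k3 = f(np.clip(xa + 0.5 * dt * k2, 0.0, None))
        k4 = f(np.clip(xa + dt * k3, 0.0, None))
        xa = np.clip(xa + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, None)
        idx = np.flatnonzero(active)
        x[idx] = xa
        if (step + 1) % check_every == 0 or step == n_steps - 1:
            speed = _residual_norm(xa, params, lam)
            done = speed < conv_tol
            active[idx[done]] = False
    converged = ~active
    return x, converged


def attractor_of(x0, attractors: AttractorSet, conv_tol: float = CONV_TOL,
                 t_max: float = T_MAX, match_tol: float = MATCH_TOL) -> int:
    """Index (into ``attractors.stable``) of the attractor reached from x0.

    Integrates the flow from ``x0`` until ||rhs|| < conv_tol or t_max, then
    matches the terminal point to the nearest stable attractor within
    ``match_tol``.  Raises RuntimeError on non-convergence and ValueError
    if the terminal state matches no stable attractor.
    """
    stable_pts = attractors.stable_points()
    if len(stable_pts) == 0:
        raise ValueError("attractor set has no stable attractor")
    x0 = _as_xy(x0)
    term, conv = integrate_to_rest(x0[None, :], attractors.params, attractors.lam,
                                   t_max=t_max, conv_tol=conv_tol)
    if not conv[0]:
        raise RuntimeError(f"non-convergent trajectory from {tuple(x0)} within t_max={t_max}")
    dists = np.linalg.norm(stable_pts - term[0], axis=1)
    best = int(np.argmin(dists))
    if dists[best] > match_tol:
        raise ValueError(
            f"unmatched terminal state {tuple(term[0])}: nearest stable attractor "
            f"at distance {dists[best]:.3e} > match_tol={match_tol}")
    return best
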