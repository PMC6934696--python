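"""Phenotype transition distances between extreme attractors.

The difficulty of switching fates is quantified geometrically: the
minimum Euclidean perturbation in (x1, x2) that moves the system from one
extreme attractor into the basin of the other, either directly or via an
intermediate attractor (perturb into an intermediate basin, relax to the
intermediate attractor point, perturb again).  Defined only for
landscapes with at least two stable attractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import SIGMOID, EnergyModel, RegulatoryParams, apply_override, production_bound
from .landscape import UNDETERMINED, BasinMap, basin_map
from .steady_states import AttractorSet, attractor_of, find_steady_states

__all__ = ["AttractorRoles", "TransitionResult", "TransitionGrid",
           "assign_roles", "transition_distance", "transition_difficulty_grid"]

#: fraction of the state-space span below which the smallest attractor
#: counts as the near-zero fate
ROLE_ZERO_FRAC = 0.05

#: absolute localisation of the basin boundary along the refinement segment
BOUNDARY_TOL = 1e-4


@dataclass(frozen=True)
class AttractorRoles:
    """Role of each stable attractor: high_x1 / high_x2 / intermediate / near_zero.

    ``roles[i]`` names the role of ``attractors.stable[i]``.  The two
    extreme fates exist whenever at least two attractors do.
    """

    roles: tuple[str, ...]

    def index_of(self, role: str) -> int:
        return self.roles.index(role)

    @property
    def high_x1(self) -> int:
        return self.index_of("high_x1")

    @property
    def high_x2(self) -> int:
        return self.index_of("high_x2")

    @property
    def stepping_stones(self) -> tuple[int, ...]:
        """Indices usable as an indirect hop: intermediate and near-zero fates."""
        return tuple(i for i, r in enumerate(self.roles)
                     if r in ("intermediate", "near_zero"))


def assign_roles(attractors: AttractorSet, role_zero_frac: float = ROLE_ZERO_FRAC) -> AttractorRoles:
    """Classify the stable attractors of a landscape by role.

    high_x1 maximizes x1 - x2 and high_x2 maximizes x2 - x1 (ties broken
    toward larger x1); the attractor minimizing x1 + x2 is near_zero when
    that sum is below ``role_zero_frac * x_max``; the rest are
    intermediate.  A monostable landscape gets the single role high_x1 by
    convention.
    """
    pts = attractors.stable_points()
    m = len(pts)
    if m == 0:
        raise ValueError("no stable attractor to assign roles to")
    if m == 1:
        return AttractorRoles(roles=("high_x1",))
    bias = 1e-12 * pts[:, 0]
    hi1 = int(np.argmax(pts[:, 0] - pts[:, 1] + bias))
    hi2 = int(np.argmax(pts[:, 1] - pts[:, 0] + bias))
    if hi1 == hi2:
        raise ValueError("degenerate geometry: high_x1 and high_x2 coincide")
    roles = ["intermediate"] * m
    roles[hi1], roles[hi2] = "high_x1", "high_x2"
    rest = [i for i in range(m) if i not in (hi1, hi2)]
    if rest:
        zero_tol = role_zero_frac * production_bound(attractors.params, attractors.lam)
        sums = pts[:, 0] + pts[:, 1]
        cand = min(rest, key=lambda i: sums[i])
        if sums[cand] < zero_tol:
            roles[cand] = "near_zero"
    return AttractorRoles(roles=tuple(roles))


@dataclass(frozen=True)
class TransitionResult:
    """Minimum perturbation distances between the extreme fates.

    ``direct``: source attractor point to the nearest point of the target
    basin.  ``indirect``: best two-leg route via a stepping-stone
    attractor (None when no intermediate exists).  ``minimum`` is the
    smaller of the two; ``route`` says which won.
    """

    direct: float
    indirect: float | None
    minimum: float
    route: str                      # "direct" | "indirect"
    source: str = "high_x1"
    target: str = "high_x2"


def _in_basin(point: np.ndarray, target: int, attractors: AttractorSet) -> bool:
    try:
        return attractor_of(point, attractors) == target
    except (RuntimeError, ValueError):
        return False


def _point_to_basin(point: np.ndarray, target: int, basin: BasinMap,
                    refine: bool = True) -> float:
    """Shortest Euclidean distance from ``point`` to the basin of ``target``.

    The nearest labelled lattice cell gives a first estimate; bisection
    along the segment from the point to that cell then localizes the basin
    boundary to :data:`BOUNDARY_TOL`, removing the lattice-cell
    overestimate.  Membership during refinement is decided by integrating
    the flow, not by the lattice.
    """
    xx, yy = np.meshgrid(basin.x1_values, basin.x2_values, indexing="ij")
    mask = basin.labels == target
    if not mask.any():
        raise ValueError(f"basin map contains no cell of attractor {target}")
    cells = np.column_stack([xx[mask], yy[mask]])
    d = np.linalg.norm(cells - point, axis=1)
    best = cells[np.argmin(d)]
    if float(np.min(d)) == 0.0:
        return 0.0
    if not refine:
        return float(np.min(d))
    att = basin.attractors
    lo, hi = 0.0, 1.0  # fractions along the segment point -> best cell
    seg = best - point
    seglen = float(np.linalg.norm(seg))
    if not _in_basin(best, target, att):       # lattice label was stale
        return float(np.min(d))
    while (hi - lo) * seglen > BOUNDARY_TOL:
        mid = 0.5 * (lo + hi)
        if _in_basin(point + mid * seg, target, att):
            hi = mid
        else:
            lo = mid
    return hi * seglen


def transition_distance(attractors: AttractorSet, basin: BasinMap | None = None,
                        allow_multihop: bool = False) -> TransitionResult:
    """Minimum perturbation to move from the high-x1 to the high-x2 fate.

    Computes (i) the direct distance from the high-x1 attractor point to
    the high-x2 basin and (ii) the best indirect route: into a
    stepping-stone basin, relaxation to that attractor point, then into
    the high-x2 basin.  With ``allow_multihop`` the indirect search uses a
    shortest path over any number of stepping stones instead of a single
    hop.  Raises ValueError for monostable landscapes, where no transition
    exists.
    """
    if attractors.n_stable < 2:
        raise ValueError("monostable landscape — transition undefined")
    if basin is None:
        basin = basin_map(attractors.params, attractors.a_star, attractors.model,
                          attractors=attractors)
    roles = assign_roles(attractors)
    pts = attractors.stable_points()
    src, tgt = roles.high_x1, roles.high_x2
    direct = _point_to_basin(pts[src], tgt, basin)
    hops = roles.stepping_stones
    indirect = None
    if hops:
        leg = {}  # (i, j): distance from attractor i's point to basin j

        def d(i, j):
            if (i, j) not in leg:
                leg[i, j] = _point_to_basin(pts[i], j, basin)
            return leg[i, j]

        if not allow_multihop:
            indirect = min(d(src, m) + d(m, tgt) for m in hops)
        else:
            # Dijkstra over {src} + stepping stones with basin-entry edges
            import heapq
            dist = {src: 0.0}
            heap = [(0.0, src)]
            nodes = set(hops) | {src}
            best = np.inf
            while heap:
                cost, u = heapq.heappop(heap)
                if cost > dist.get(u, np.inf):
                    continue
                best = min(best, cost + d(u, tgt))
                for v in nodes - {u}:
                    c = cost + d(u, v)
                    if c < dist.get(v, np.inf):
                        dist[v] = c
                        heapq.heappush(heap, (c, v))
            indirect = float(best)
    minimum = direct if indirect is None or direct <= indirect else indirect
    route = "direct" if minimum == direct else "indirect"
    return TransitionResult(direct=float(direct), indirect=indirect,
                            minimum=float(minimum), route=route)


@dataclass
class TransitionGrid:
    """Minimum transition distances over a parameter plane.

    NaN distances (empty route) mark monostable nodes where no transition
    is defined.
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    min_distance: np.ndarray
    route: np.ndarray
    fixed_params: RegulatoryParams
    model: EnergyModel = SIGMOID

    def to_frame(self) -> pd.DataFrame:
        i, j = np.meshgrid(np.arange(len(self.axis1_values)),
                           np.arange(len(self.axis2_values)), indexing="ij")
        return pd.DataFrame({self.axis1_name: self.axis1_values[i.ravel()],
                             self.axis2_name: self.axis2_values[j.ravel()],
                             "min_distance": self.min_distance.ravel(),
                             "route": self.route.ravel()})


def transition_difficulty_grid(params: RegulatoryParams, axis1, axis2,
                               model: EnergyModel = SIGMOID, a_star: float = 1.0,
                               basin_resolution: int = 41,
                               **solver_kw) -> TransitionGrid:
    """Map the minimum transition distance over a parameter plane.

    Each node solves the steady-state problem, builds a basin map and
    evaluates :func:`transition_distance`; monostable nodes are NaN.  This
    is the expensive landscape — keep the axes and ``basin_resolution``
    modest.
    """
    name1, vals1 = (axis1[0], np.asarray(axis1[1], dtype=float))
    name2, vals2 = (axis2[0], np.asarray(axis2[1], dtype=float))
    dmin = np.full((len(vals1), len(vals2)), np.nan)
    route = np.full((len(vals1), len(vals2)), "", dtype=object)
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            p, energy = params, a_star
            for name, value in ((name1, v1), (name2, v2)):
                if name == "a_star":
                    energy = value
                else:
                    p = apply_override(p, name, value)
            att = find_steady_states(p, energy, model, **solver_kw)
            if att.n_stable < 2:
                continue
            bm = basin_map(p, energy, model, resolution=basin_resolution,
                           attractors=att)
            res = transition_distance(att, bm)
            dmin[i, j] = res.minimum
            route[i, j] = res.route
    return TransitionGrid(axis1_name=name1, axis1_values=vals1,
                          axis2_name=name2, axis2_values=vals2,
                          min_distance=dmin, route=route,
                          fixed_params=params, model=model)
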