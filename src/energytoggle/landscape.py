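"""Attractor-count landscapes and basin-of-attraction maps.

The central object is the count grid: the number of stable steady states
at every node of a two-parameter plane, typically (b, A*) at fixed a —
the "phase portrait" of decision-making capacity.  The basin map labels a
lattice of initial conditions in the (x1, x2) plane by the stable
attractor their trajectories reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import SIGMOID, EnergyModel, RegulatoryParams, apply_override, production_bound
from .steady_states import (
    MATCH_TOL,
    AttractorSet,
    find_steady_states,
    integrate_to_rest,
)

__all__ = ["CountGrid", "BasinMap", "attractor_count_grid",
           "low_energy_monostability_threshold", "basin_map", "scan_theta",
           "MONOSTABLE_EVERYWHERE"]

#: threshold marker for axis columns that never leave monostability
MONOSTABLE_EVERYWHERE = "monostable_everywhere"

#: label for basin cells whose trajectory could not be attributed
UNDETERMINED = -1

#: label for separatrix cells whose trajectory converges to a functionally
#: unstable steady state (e.g. exact-diagonal starts in a symmetric bistable
#: landscape lie on the saddle's stable manifold)
BOUNDARY = -2


def _axis(spec) -> tuple[str, np.ndarray]:
    name, values = spec
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError(f"axis {name!r} needs a 1-D array of at least 2 values")
    return str(name), values


def _solve_at(params: RegulatoryParams, overrides: dict, a_star: float,
              model: EnergyModel, **solver_kw) -> AttractorSet:
    p = params
    for name, value in overrides.items():
        p = apply_override(p, name, value)
    return find_steady_states(p, a_star, model, **solver_kw)


@dataclass
class CountGrid:
    """Stable-state counts over a 2-parameter plane.

    ``counts[i, j]`` is the number of stable attractors at
    (axis1_values[i], axis2_values[j]); ``fixed_params`` snapshots every
    constant not scanned by an axis.
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    counts: np.ndarray
    fixed_params: RegulatoryParams
    a_star: float | None = None     # fixed energy when neither axis is a_star
    model: EnergyModel = SIGMOID

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.axis1_values), len(self.axis2_values)):
            raise ValueError("counts shape must match the axes")
        if np.any(self.counts < 1):
            raise ValueError("every grid node must support at least one stable state")

    def distinct_counts(self) -> set[int]:
        return {int(c) for c in np.unique(self.counts)}

    def max_count(self) -> int:
        return int(self.counts.max())

    def to_frame(self) -> pd.DataFrame:
        i, j = np.meshgrid(np.arange(len(self.axis1_values)),
                           np.arange(len(self.axis2_values)), indexing="ij")
        return pd.DataFrame({self.axis1_name: self.axis1_values[i.ravel()],
                             self.axis2_name: self.axis2_values[j.ravel()],
                             "count": self.counts.ravel()})


def attractor_count_grid(params: RegulatoryParams, axis1, axis2,
                         model: EnergyModel = SIGMOID, a_star: float = 1.0,
                         **solver_kw) -> CountGrid:
    """Count stable steady states at every node of a parameter plane.

    Each axis is a ``(name, values)`` pair; a name may be any circuit
    constant (symmetric shorthands like ``"b"`` set both genes) or
    ``"a_star"``.  Solver failures propagate with the grid coordinates
    attached.
    """
    name1, vals1 = _axis(axis1)
    name2, vals2 = _axis(axis2)
    if min(len(vals1), len(vals2)) < 10:
        raise ValueError("landscape axes need at least 10 points each")
    counts = np.zeros((len(vals1), len(vals2)), dtype=int)
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            overrides, energy = {}, a_star
            for name, value in ((name1, v1), (name2, v2)):
                if name == "a_star":
                    energy = value
                else:
                    overrides[name] = value
            try:
                counts[i, j] = _solve_at(params, overrides, energy, model, **solver_kw).n_stable
            except Exception as exc:
                raise RuntimeError(
                    f"count failed at {name1}={v1}, {name2}={v2}") from exc
    return CountGrid(axis1_name=name1, axis1_values=vals1, axis2_name=name2,
                     axis2_values=vals2, counts=counts, fixed_params=params,
                     a_star=None if "a_star" in (name1, name2) else a_star,
                     model=model)


def low_energy_monostability_threshold(grid: CountGrid):
    """Per-axis1 energy threshold below which the system is monostable.

    For each axis1 value the threshold is the first A* grid value at which
    the count leaves 1 (every smaller grid value is monostable).  Columns
    monostable over the whole scanned range get the marker
    :data:`MONOSTABLE_EVERYWHERE` with the last grid value as threshold.
    Returns a DataFrame (axis1, threshold, marker).  The separatrix curve
    of the phase portrait is the threshold as a function of axis1.
    """
    if grid.axis2_name != "a_star":
        raise ValueError("threshold extraction requires axis2 == 'a_star'")
    a = grid.axis2_values
    rows = []
    for i, v in enumerate(grid.axis1_values):
        nonmono = np.flatnonzero(grid.counts[i] != 1)
        if len(nonmono) == 0:
            rows.append((v, float(a[-1]), MONOSTABLE_EVERYWHERE))
        else:
            rows.append((v, float(a[nonmono[0]]), ""))
    return pd.DataFrame(rows, columns=[grid.axis1_name, "threshold", "marker"])


@dataclass
class BasinMap:
    """Initial-condition lattice labelled by terminal stable attractor.

    ``labels[i, j]`` is an index into ``attractors.stable`` for the
    trajectory started at (x1_values[i], x2_values[j]);
    :data:`BOUNDARY` marks separatrix cells (limit is an unstable steady
    state) and :data:`UNDETERMINED` non-convergent/unmatched cells.
    """

    x1_values: np.ndarray
    x2_values: np.ndarray
    labels: np.ndarray
    attractors: AttractorSet

    @property
    def n_undetermined(self) -> int:
        return int(np.sum(self.labels == UNDETERMINED))

    @property
    def n_boundary(self) -> int:
        return int(np.sum(self.labels == BOUNDARY))

    def label_set(self) -> set[int]:
        return {int(v) for v in np.unique(self.labels) if v >= 0}

    def to_frame(self) -> pd.DataFrame:
        i, j = np.meshgrid(np.arange(len(self.x1_values)),
                           np.arange(len(self.x2_values)), indexing="ij")
        return pd.DataFrame({"x1_0": self.x1_values[i.ravel()],
                             "x2_0": self.x2_values[j.ravel()],
                             "label": self.labels.ravel()})


def _label_points(points: np.ndarray, attractors: AttractorSet,
                  match_tol: float, t_max: float) -> np.ndarray:
    """Batch-integrate initial conditions and match to stable attractors.

    Limits matching an unstable steady state mark separatrix cells: the
    start lay on a stable manifold of a saddle (exactly symmetric starts
    in a symmetric landscape do this deterministically).
    """
    stable_pts = attractors.stable_points()
    term, conv = integrate_to_rest(points, attractors.params, attractors.lam, t_max=t_max)
    d = np.linalg.norm(term[:, None, :] - stable_pts[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    matched = d[np.arange(len(points)), nearest] <= match_tol
    labels = np.where(conv & matched, nearest, UNDETERMINED)
    unstable_pts = np.array([s.state for s in attractors.steady_states
                             if not s.is_stable])
    if len(unstable_pts):
        du = np.linalg.norm(term[:, None, :] - unstable_pts[None, :, :], axis=2)
        on_separatrix = conv & ~matched & (du.min(axis=1) <= match_tol)
        labels[on_separatrix] = BOUNDARY
    return labels


def basin_map(params: RegulatoryParams, a_star, model: EnergyModel = SIGMOID,
              resolution: int = 101, margin: float = 1.2,
              match_tol: float = MATCH_TOL, t_max: float = 500.0,
              attractors: AttractorSet | None = None,
              max_undetermined_frac: float = 0.01) -> BasinMap:
    """Partition [0, margin*x_max]^2 into basins of attraction.

    Every lattice cell is integrated to rest and labelled by the stable
    attractor reached.  Raises RuntimeError if more than
    ``max_undetermined_frac`` of the cells cannot be attributed, which
    signals inadequate integrator settings.
    """
    if attractors is None:
        attractors = find_steady_states(params, a_star, model)
    if attractors.n_stable < 1:
        raise ValueError("basin map needs at least one stable attractor")
    span = margin * max(production_bound(params, attractors.lam), 1e-2)
    g1 = np.linspace(0.0, span, resolution)
    g2 = np.linspace(0.0, span, resolution)
    xx, yy = np.meshgrid(g1, g2, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    labels = _label_points(pts, attractors, match_tol, t_max).reshape(resolution, resolution)
    bm = BasinMap(x1_values=g1, x2_values=g2, labels=labels, attractors=attractors)
    frac = bm.n_undetermined / labels.size
    if frac > max_undetermined_frac:
        raise RuntimeError(
            f"{frac:.1%} of basin cells undetermined (> {max_undetermined_frac:.0%}); "
            "increase t_max or match_tol")
    return bm


def scan_theta(which: str, values, params: RegulatoryParams, a_star_values,
               model: EnergyModel = SIGMOID, **solver_kw) -> CountGrid:
    """Attractor-count grid over a binding-strength axis vs energy.

    ``which`` is ``"theta_a"`` (activator dissociation constant) or
    ``"theta_b"`` (inhibitor); both gene copies are scanned together.
    """
    if which not in ("theta_a", "theta_b"):
        raise ValueError("which must be 'theta_a' or 'theta_b'")
    return attractor_count_grid(params, (which, values), ("a_star", a_star_values),
                                model=model, **solver_kw)
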