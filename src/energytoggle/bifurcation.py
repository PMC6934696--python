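"""Bifurcation sweeps over the energy level A*.

Each energy value is solved independently (no branch continuation); the
sweep records the full steady-state set, the stable count, the energy
values where the stable count changes, and a run-length encoding of the
count sequence used to detect re-entrant behaviour (a count value that
recurs after an intervening different count, e.g. 1,3,2,3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import SIGMOID, EnergyModel, RegulatoryParams
from .steady_states import AttractorSet, find_steady_states

__all__ = ["BifurcationSweep", "CountRun", "sweep_energy", "count_sequence",
           "attractor_separation"]

#: A* step used throughout the published-style sweeps
DEFAULT_STEP = 5e-3


@dataclass(frozen=True)
class CountRun:
    """A maximal run of constant stable count over an A* interval."""

    count: int
    a_star_min: float
    a_star_max: float


@dataclass
class BifurcationSweep:
    """Steady-state sets over an ordered A* grid."""

    a_star_values: np.ndarray
    attractor_sets: list[AttractorSet]
    params: RegulatoryParams
    model: EnergyModel = SIGMOID

    def __post_init__(self):
        self.a_star_values = np.asarray(self.a_star_values, dtype=float)
        if np.any(np.diff(self.a_star_values) <= 0):
            raise ValueError("a_star_values must be strictly increasing")
        if len(self.attractor_sets) != len(self.a_star_values):
            raise ValueError("one attractor set required per a_star value")

    @property
    def stable_counts(self) -> np.ndarray:
        return np.array([a.n_stable for a in self.attractor_sets], dtype=int)

    @property
    def change_points(self) -> np.ndarray:
        """A* values at which the stable count first differs from its left neighbour."""
        c = self.stable_counts
        return self.a_star_values[1:][np.diff(c) != 0]

    def to_frame(self) -> pd.DataFrame:
        """Long format (a_star, x1, x2, stability, leading_re, residual)."""
        return pd.concat([a.to_frame() for a in self.attractor_sets], ignore_index=True)


def sweep_energy(params: RegulatoryParams, model: EnergyModel = SIGMOID,
                 a_star_min: float = 0.0, a_star_max: float = 1.0,
                 step: float = DEFAULT_STEP, **solver_kw) -> BifurcationSweep:
    """Solve the steady-state problem on a uniform A* grid.

    The grid is ``a_star_min, a_star_min+step, ..., a_star_max`` (endpoint
    included).  Solver failures propagate with the offending A* attached.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((a_star_max - a_star_min) / step))
    values = a_star_min + step * np.arange(n + 1)
    values = values[values <= a_star_max + 1e-12]
    sets = []
    for a_star in values:
        try:
            sets.append(find_steady_states(params, a_star, model, **solver_kw))
        except Exception as exc:
            raise RuntimeError(f"steady-state solve failed at a_star={a_star}") from exc
    return BifurcationSweep(a_star_values=values, attractor_sets=sets,
                            params=params, model=model)


def count_sequence(sweep: BifurcationSweep) -> tuple[list[CountRun], bool]:
    """Run-length encode the stable-count sequence of a sweep.

    Returns ``(runs, re_entrant)`` where ``re_entrant`` is True iff some
    count value appears in two different (necessarily non-adjacent) runs.
    """
    counts = sweep.stable_counts
    a = sweep.a_star_values
    runs: list[CountRun] = []
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            runs.append(CountRun(count=int(counts[start]),
                                 a_star_min=float(a[start]),
                                 a_star_max=float(a[i - 1])))
            start = i
    re_entrant = len({r.count for r in runs}) < len(runs)
    return runs, re_entrant


def _extreme_pair(attractors: AttractorSet):
    """Indices of the high-x1 and high-x2 stable attractors (ties -> larger x1)."""
    pts = attractors.stable_points()
    if len(pts) < 2:
        return None
    bias = 1e-12 * pts[:, 0]  # deterministic tie-break toward larger x1
    hi1 = int(np.argmax(pts[:, 0] - pts[:, 1] + bias))
    hi2 = int(np.argmax(pts[:, 1] - pts[:, 0] + bias))
    if hi1 == hi2:
        return None
    return hi1, hi2


def attractor_separation(sweep: BifurcationSweep, which: str = "extremes") -> np.ndarray:
    """Euclidean distance between the two extreme attractors at each A*.

    Entries where fewer than two stable attractors exist (or the extremes
    degenerate) are NaN.  Only the ``"extremes"`` pair selector is
    implemented — the high-x1 vs high-x2 attractors.
    """
    if which != "extremes":
        raise ValueError("only the 'extremes' pair selector is supported")
    out = np.full(len(sweep.a_star_values), np.nan)
    for i, att in enumerate(sweep.attractor_sets):
        pair = _extreme_pair(att)
        if pair is not None:
            pts = att.stable_points()
            out[i] = float(np.linalg.norm(pts[pair[0]] - pts[pair[1]]))
    return out
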