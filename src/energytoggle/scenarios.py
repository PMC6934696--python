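"""Named parameter regimes and random parameter samplers.

Every analysis regime exercised by the package ships here as a fully
self-describing :class:`Scenario` — circuit constants, energy model, axis
specifications and a provenance note saying whether the values are the
canonical published constants or a documented guess.  The random sampler
provides seeded draws for property-based testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import EnergyModel, RegulatoryParams, SIGMOID

__all__ = ["Scenario", "builtin_scenarios", "get_scenario", "scenario_names",
           "random_params", "DEFAULT_RANGES"]

#: sampling ranges spanning the published parameter scans
DEFAULT_RANGES = {
    "a": (0.1, 3.0),
    "b": (0.1, 3.0),
    "k": (0.2, 2.0),
    "theta_a": (0.1, 1.5),
    "theta_b": (0.1, 1.5),
    "n": (1, 2, 3, 4),
}

_B_AXIS = ("b", np.linspace(0.0, 3.0, 61))
_ASTAR_AXIS = ("a_star", np.linspace(0.0, 1.0, 51))

#: the six conditional-promoter activities of the landscape panel series;
#: the published series states only "increasing values", so this spread is
#: guessed
PANEL_A_VALUES = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0)


@dataclass(frozen=True)
class Scenario:
    """A self-contained analysis regime.

    ``kind`` selects the analysis ("sweep" | "landscape" | "transitions");
    ``axes`` carries the axis specs the analysis expects; ``provenance``
    records where the numbers come from, with the word "guessed" whenever
    a value is not fixed by the published setting.
    """

    name: str
    params: RegulatoryParams
    model: EnergyModel = SIGMOID
    kind: str = "sweep"
    axes: dict = field(default_factory=dict)
    provenance: str = ""

    def reduced_axes(self, factor: int = 2) -> dict:
        """Axes thinned by ``factor`` (endpoints kept) for quick runs."""
        out = {}
        for key, (name, vals) in self.axes.items():
            vals = np.asarray(vals)
            idx = np.unique(np.r_[np.arange(0, len(vals), factor), len(vals) - 1])
            out[key] = (name, vals[idx])
        return out


def builtin_scenarios() -> list[Scenario]:
    """Every named regime used by the bifurcation/landscape/transition analyses."""
    d = RegulatoryParams.defaults
    sym = RegulatoryParams.symmetric
    sweep_axis = {"a_star": ("a_star", np.arange(0.0, 1.0 + 1e-12, 5e-3))}
    scenarios = [
        Scenario(
            name="defaults_sweep", params=d(), kind="sweep", axes=sweep_axis,
            provenance="canonical symmetric default constants (a=b=k=1, theta=0.5, n=4); "
                       "A* swept 0..1 in steps of 5e-3"),
        Scenario(
            name="b_energy_landscape", params=d(), kind="landscape",
            axes={"axis1": _B_AXIS, "axis2": _ASTAR_AXIS},
            provenance="decision-capacity phase portrait at a=1: b in [0,3] x A* in [0,1], "
                       "all other constants at defaults"),
        Scenario(
            name="promoter_activity_panels", params=d(), kind="landscape",
            axes={"axis1": _B_AXIS, "axis2": _ASTAR_AXIS,
                  "panel_a": ("a", np.array(PANEL_A_VALUES))},
            provenance="(b, A*) landscape panel series over increasing conditional-promoter "
                       f"activity; the six a values {PANEL_A_VALUES} are guessed"),
        Scenario(
            name="external_atp", params=d(), kind="landscape",
            model=EnergyModel(kind="shifted", floor=0.1, ceiling=1.2),
            axes={"axis1": _B_AXIS, "axis2": _ASTAR_AXIS},
            provenance="external ATP uptake: shifted energy scaling, nonzero at A*=0 and "
                       "exceeding 1 at A*=1; floor=0.1 and ceiling=1.2 are guessed "
                       "demonstration values"),
        Scenario(
            name="high_a_reentrant", params=sym(b=1.0), kind="sweep",
            axes={**sweep_axis, "scan_a": ("a", np.array([1.5, 2.0, 2.5, 3.0]))},
            provenance="re-entrant stable-count search: A* sweeps at b=1 over a scan of "
                       "high conditional-promoter activities; the scanned a values are "
                       "guessed (the published setting states only 'high a')"),
    ]
    # the cooperativity scans use a 50-point A* axis: the defaults with n=1
    # are exactly degenerate at (b=0, A*=1/2) — lambda*a/theta == k makes the
    # origin a non-hyperbolic root that no eigenvalue rule can classify —
    # and that knife-edge node is deliberately left off the lattice
    coop_astar = ("a_star", np.linspace(0.0, 1.0, 50))
    for n in (1, 2, 3, 4):
        scenarios.append(Scenario(
            name=f"cooperativity_{n}", params=sym(n=n), kind="landscape",
            axes={"axis1": _B_AXIS, "axis2": coop_astar},
            provenance=f"Hill-coefficient scan member n={n}, other constants at defaults"))
    for which in ("theta_a", "theta_b"):
        scenarios.append(Scenario(
            name=f"{which}_scan", params=d(), kind="landscape",
            axes={"axis1": (which, np.linspace(0.1, 1.5, 29)), "axis2": _ASTAR_AXIS},
            provenance=f"binding-strength scan over {which} in [0.1, 1.5] x A* in [0,1]; "
                       "the theta range is guessed around the default 0.5"),)
    for a in (1, 2, 3):
        scenarios.append(Scenario(
            name=f"transition_grid_a{a}", params=sym(a=float(a)), kind="transitions",
            axes={"axis1": ("b", np.linspace(0.0, 3.0, 13)),
                  "axis2": ("a_star", np.linspace(0.0, 1.0, 11))},
            provenance=f"transition-difficulty grid at a={a}; the grid resolution is a "
                       "package choice (the published resolution is unstated, guessed)"))
    return scenarios


def scenario_names() -> list[str]:
    return [s.name for s in builtin_scenarios()]


def get_scenario(name: str) -> Scenario:
    for s in builtin_scenarios():
        if s.name == name:
            return s
    raise KeyError(f"unknown scenario {name!r}; available: {', '.join(scenario_names())}")


def random_params(seed=None, ranges: dict | None = None,
                  symmetric: bool = True, rng: np.random.Generator | None = None) -> RegulatoryParams:
    """Draw a random parameter set (log-uniform rates, uniform n choice).

    Deterministic for a given ``seed``; pass an ``rng`` instead to draw
    streams.  With ``symmetric`` (default) both genes share each constant;
    otherwise each gene's copy is drawn independently.
    """
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    for key in ("a", "b", "k", "theta_a", "theta_b"):
        lo, hi = ranges[key]
        if not (0 < lo <= hi):
            raise ValueError(f"range for {key!r} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
    if rng is None:
        rng = np.random.default_rng(seed)

    def draw(key):
        lo, hi = ranges[key]
        m = 1 if symmetric else 2
        v = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m))
        return (float(v[0]), float(v[0])) if symmetric else (float(v[0]), float(v[1]))

    a1, a2 = draw("a")
    b1, b2 = draw("b")
    k1, k2 = draw("k")
    ta1, ta2 = draw("theta_a")
    tb1, tb2 = draw("theta_b")
    n = float(rng.choice(np.asarray(ranges["n"], dtype=float)))
    return RegulatoryParams(a1=a1, a2=a2, b1=b1, b2=b2, k1=k1, k2=k2,
                            theta_a1=ta1, theta_a2=ta2, theta_b1=tb1, theta_b2=tb2, n=n)
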