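"""Energy-dependent two-gene toggle-switch model.

The circuit consists of two genes whose protein products self-activate
(via a conditional promoter, Hill kinetics) and cross-repress each other's
constitutive promoter, with first-order degradation:

    dx1/dt = lam * a1 * x1^n / (theta_a1^n + x1^n)
           + lam * b1 * theta_b1^n / (theta_b1^n + x2^n)
           - k1 * x1

and symmetrically for ``x2``.  The dimensionless factor ``lam = lambda(A*)``
scales both production terms and models the ATP dependence of transcription
and translation; ``A*`` is the cell's free-energy availability as a fraction
of its maximum, normally in [0, 1].  Degradation is taken to be energy
independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "RegulatoryParams",
    "EnergyModel",
    "EnergyLevel",
    "SystemState",
    "SIGMOID",
    "LINEAR",
    "lambda_energy",
    "rhs",
    "jacobian",
    "map_atp_to_astar",
    "production_bound",
    "apply_override",
]

# ATP range observed in E. coli populations (micromolar); used as the default
# anchor points when mapping an ATP concentration onto A*.
ATP_LO_UM = 320.0
ATP_HI_UM = 2760.0


@dataclass(frozen=True)
class RegulatoryParams:
    """Rate constants of the two-gene circuit.

    ``a_i``: maximum expression rate of the self-activated (conditional)
    promoter; ``b_i``: basal rate of the constitutive promoter, repressible
    by the other gene's product; ``k_i``: first-order degradation rate;
    ``theta_a_i`` / ``theta_b_i``: dissociation constants of the activator /
    inhibitor to the promoter region; ``n``: Hill coefficient shared by all
    four regulatory terms.
    """

    a1: float = 1.0
    a2: float = 1.0
    b1: float = 1.0
    b2: float = 1.0
    k1: float = 1.0
    k2: float = 1.0
    theta_a1: float = 0.5
    theta_a2: float = 0.5
    theta_b1: float = 0.5
    theta_b2: float = 0.5
    n: float = 4.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            # basal rates b_i may vanish (no constitutive expression, the
            # decoupled limit); every other rate/threshold must be positive
            if f.name in ("b1", "b2"):
                if v < 0:
                    raise ValueError(f"parameter {f.name} must be non-negative, got {v!r}")
            elif f.name != "n" and v <= 0:
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v!r}")
        if self.n < 1:
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n!r}")

    @classmethod
    def defaults(cls) -> "RegulatoryParams":
        """The canonical symmetric parameter set: a=b=k=1, theta=0.5, n=4."""
        return cls()

    @classmethod
    def symmetric(cls, a=1.0, b=1.0, k=1.0, theta_a=0.5, theta_b=0.5, n=4.0) -> "RegulatoryParams":
        return cls(a1=a, a2=a, b1=b, b2=b, k1=k, k2=k,
                   theta_a1=theta_a, theta_a2=theta_a,
                   theta_b1=theta_b, theta_b2=theta_b, n=n)

    @property
    def is_symmetric(self) -> bool:
        return (self.a1 == self.a2 and self.b1 == self.b2 and self.k1 == self.k2
                and self.theta_a1 == self.theta_a2 and self.theta_b1 == self.theta_b2)

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RegulatoryParams":
        return cls(**{f.name: float(d[f.name]) for f in fields(cls)})


# Symmetric shorthand names accepted by parameter scans; each sets both gene
# copies of the constant at once.
_SYMMETRIC_NAMES = {
    "a": ("a1", "a2"),
    "b": ("b1", "b2"),
    "k": ("k1", "k2"),
    "theta_a": ("theta_a1", "theta_a2"),
    "theta_b": ("theta_b1", "theta_b2"),
    "n": ("n",),
}


def apply_override(params: RegulatoryParams, name: str, value: float) -> RegulatoryParams:
    """Return a copy of ``params`` with one constant replaced.

    ``name`` may be an individual field (``"a1"``) or a symmetric shorthand
    (``"a"``, ``"theta_b"``, ...) that sets both gene copies.
    """
    if name in _SYMMETRIC_NAMES:
        return replace(params, **{f: value for f in _SYMMETRIC_NAMES[name]})
    if name in {f.name for f in fields(RegulatoryParams)}:
        return replace(params, **{name: value})
    raise ValueError(f"unknown parameter name {name!r}")


_ENERGY_KINDS = ("sigmoid", "linear", "shifted")


@dataclass(frozen=True)
class EnergyModel:
    """Specification of the transcription-rate scaling ``lambda(A*)``.

    kind="sigmoid": lambda = 1 / (1 + exp(-(s1*A* + s2))); the defaults
    s1=16, s2=-8 give the midpoint lambda(0.5)=0.5 and lambda in (0, 1).

    kind="linear": lambda = A* clamped to [0, 1].

    kind="shifted": floor + (ceiling - floor) * sigmoid(s1*A* + s2) — an
    affine rescale of the sigmoid modelling an external ATP source, nonzero
    at A*=0 and allowed to exceed 1.
    """

    kind: str = "sigmoid"
    s1: float = 16.0
    s2: float = -8.0
    floor: float = 0.0
    ceiling: float = 1.0

    def __post_init__(self):
        if self.kind not in _ENERGY_KINDS:
            raise ValueError(f"kind must be one of {_ENERGY_KINDS}, got {self.kind!r}")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
        if self.ceiling <= self.floor:
            raise ValueError("ceiling must exceed floor")

    def __call__(self, a_star):
        return lambda_energy(a_star, self)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "s1": float(self.s1), "s2": float(self.s2),
                "floor": float(self.floor), "ceiling": float(self.ceiling)}

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyModel":
        return cls(kind=d.get("kind", "sigmoid"), s1=float(d.get("s1", 16.0)),
                   s2=float(d.get("s2", -8.0)), floor=float(d.get("floor", 0.0)),
                   ceiling=float(d.get("ceiling", 1.0)))


SIGMOID = EnergyModel(kind="sigmoid")
LINEAR = EnergyModel(kind="linear")


@dataclass(frozen=True)
class EnergyLevel:
    """Scaled free-energy availability A* with a viability marker.

    ``sub_critical`` marks levels at or below the minimum energy a living
    cell is taken to sustain (A* <= 0 under the default ATP mapping).
    """

    a_star: float
    sub_critical: bool = False

    def __post_init__(self):
        if not np.isfinite(self.a_star):
            raise ValueError("a_star must be finite")

    def __float__(self) -> float:
        return float(self.a_star)


@dataclass(frozen=True)
class SystemState:
    """Protein levels (x1, x2); both non-negative and finite."""

    x1: float
    x2: float

    def __post_init__(self):
        if not (np.isfinite(self.x1) and np.isfinite(self.x2)):
            raise ValueError("state components must be finite")
        if self.x1 < 0 or self.x2 < 0:
            raise ValueError("state components must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2], dtype=float)


def _as_xy(state) -> np.ndarray:
    """Coerce a SystemState / pair / (..., 2) array to a float array."""
    if isinstance(state, SystemState):
        return state.as_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape[-1] != 2:
        raise ValueError("state must have two components (x1, x2)")
    return arr


def lambda_energy(a_star, model: EnergyModel = SIGMOID):
    """Evaluate the energy-scaling factor lambda(A*). Vectorized over a_star.

    Strictly increasing in A* on [0, 1] for every kind (the linear kind is
    flat only outside that interval, where it clamps).
    """
    a = np.asarray(a_star, dtype=float) if not isinstance(a_star, EnergyLevel) else np.float64(a_star.a_star)
    if not np.all(np.isfinite(a)):
        raise ValueError("a_star must be finite")
    if model.kind in ("sigmoid", "linear") and np.any((a < 0) | (a > 1)):
        warnings.warn(f"a_star outside [0, 1] with kind={model.kind!r}; "
                      "interpretation as a scaled energy fraction breaks down",
                      stacklevel=2)
    if model.kind == "linear":
        out = np.clip(a, 0.0, 1.0)
    else:
        sig = 1.0 / (1.0 + np.exp(-(model.s1 * a + model.s2)))
        if model.kind == "sigmoid":
            out = sig
        else:  # shifted
            out = model.floor + (model.ceiling - model.floor) * sig
    return out if out.ndim else float(out)


def _production(x1, x2, p: RegulatoryParams, lam):
    """Production terms of both genes (no degradation); no input validation.

    The activation Hill term at x=0 evaluates to 0 for every n >= 1 (the
    limit convention) because 0**n == 0.
    """
    n = p.n
    ta1, ta2 = p.theta_a1**n, p.theta_a2**n
    tb1, tb2 = p.theta_b1**n, p.theta_b2**n
    x1n, x2n = x1**n, x2**n
    prod1 = lam * (p.a1 * x1n / (ta1 + x1n) + p.b1 * tb1 / (tb1 + x2n))
    prod2 = lam * (p.a2 * x2n / (ta2 + x2n) + p.b2 * tb2 / (tb2 + x1n))
    return prod1, prod2


def _rhs_xy(x1, x2, p: RegulatoryParams, lam):
    prod1, prod2 = _production(x1, x2, p, lam)
    return prod1 - p.k1 * x1, prod2 - p.k2 * x2


def rhs(state, params: RegulatoryParams, lam: float):
    """Time derivatives (dx1/dt, dx2/dt) of the energy-scaled circuit.

    ``state`` may be a SystemState, a pair, or an array of shape (..., 2);
    the return value matches the trailing shape.  Raises on negative or
    non-finite state components and on lam < 0.
    """
    x = _as_xy(state)
    if not np.all(np.isfinite(x)):
        raise ValueError("state components must be finite")
    if np.any(x < 0):
        raise ValueError("state components must be non-negative")
    lam = float(lam)
    if not math.isfinite(lam) or lam < 0:
        raise ValueError("lam must be finite and >= 0")
    d1, d2 = _rhs_xy(x[..., 0], x[..., 1], params, lam)
    return np.stack([d1, d2], axis=-1)


def _jacobian_xy(x1, x2, p: RegulatoryParams, lam):
    """Entries of the 2x2 Jacobian, vectorized; no input validation.

    Hill derivatives: d/dx [x^n/(t^n+x^n)] = n t^n x^(n-1) / (t^n+x^n)^2 and
    d/dx [t^n/(t^n+x^n)] = -n t^n x^(n-1) / (t^n+x^n)^2.  At x=0 the power
    x^(n-1) is 0 for n>1 and 1 for n=1 (numpy's 0**0), which reproduces the
    limit derivatives exactly.
    """
    n = p.n
    ta1, ta2 = p.theta_a1**n, p.theta_a2**n
    tb1, tb2 = p.theta_b1**n, p.theta_b2**n
    x1n, x2n = x1**n, x2**n
    x1m, x2m = x1**(n - 1.0), x2**(n - 1.0)
    dact1 = n * ta1 * x1m / (ta1 + x1n) ** 2
    dact2 = n * ta2 * x2m / (ta2 + x2n) ** 2
    drep1 = -n * tb1 * x2m / (tb1 + x2n) ** 2   # d(repression of gene 1)/dx2
    drep2 = -n * tb2 * x1m / (tb2 + x1n) ** 2   # d(repression of gene 2)/dx1
    j11 = lam * p.a1 * dact1 - p.k1
    j12 = lam * p.b1 * drep1
    j21 = lam * p.b2 * drep2
    j22 = lam * p.a2 * dact2 - p.k2
    return j11, j12, j21, j22


def jacobian(state, params: RegulatoryParams, lam: float):
    """Analytic Jacobian of :func:`rhs`; shape (..., 2, 2).

    The diagonal carries the degradation rates -k_i; the off-diagonal
    entries are the cross-repression derivatives and are always <= 0.
    """
    x = _as_xy(state)
    if not np.all(np.isfinite(x)):
        raise ValueError("state components must be finite")
    if np.any(x < 0):
        raise ValueError("state components must be non-negative")
    if params.n < 1:
        raise ValueError("Hill coefficient n must be >= 1")
    j11, j12, j21, j22 = _jacobian_xy(x[..., 0], x[..., 1], params, float(lam))
    row1 = np.stack([j11, j12], axis=-1)
    row2 = np.stack([j21, j22], axis=-1)
    return np.stack([row1, row2], axis=-2)


def map_atp_to_astar(conc_um: float, lo: float = ATP_LO_UM, hi: float = ATP_HI_UM) -> EnergyLevel:
    """Map an absolute ATP concentration (micromolar) onto A* linearly.

    ``lo`` maps to A*=0 (the critical energy to continue as a living cell)
    and ``hi`` to A*=1.  Concentrations at or below ``lo`` are flagged
    sub-critical; values below ``lo`` give A* < 0.
    """
    if not (hi > lo > 0):
        raise ValueError("need hi > lo > 0")
    conc_um = float(conc_um)
    if not math.isfinite(conc_um) or conc_um <= 0:
        raise ValueError("ATP concentration must be positive and finite")
    a_star = (conc_um - lo) / (hi - lo)
    return EnergyLevel(a_star=a_star, sub_critical=conc_um <= lo)


def production_bound(params: RegulatoryParams, lam: float) -> float:
    """Upper bound max_i lam*(a_i+b_i)/k_i on any steady-state component."""
    return float(lam) * max((params.a1 + params.b1) / params.k1,
                            (params.a2 + params.b2) / params.k2)
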