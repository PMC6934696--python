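"""Configuration files and tabular writers.

Configs are flat YAML (or JSON — YAML is a superset): a ``params`` block
with the exact circuit-constant field names, an optional ``energy`` block,
and run settings.  All CSV output uses a header row, '.' decimal and
UTF-8.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model_core import EnergyModel, RegulatoryParams
from .steady_states import DEDUP_TOL, MATCH_TOL, RESIDUAL_TOL, STABILITY_EPS

__all__ = ["RunConfig", "load_config", "save_config", "write_csv", "write_summary"]


@dataclass
class RunConfig:
    """Settings of one command-line run; round-trips through YAML losslessly."""

    scenario: str | None = None
    params: RegulatoryParams | None = None
    energy: EnergyModel | None = None
    out: str = "."
    resolution: int | None = None     # axis thinning factor (None = full)
    seed: int = 0
    plot: bool = False
    residual_tol: float = RESIDUAL_TOL
    dedup_tol: float = DEDUP_TOL
    stability_eps: float = STABILITY_EPS
    match_tol: float = MATCH_TOL

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict() if self.params else None
        d["energy"] = self.energy.to_dict() if self.energy else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("params"):
            d["params"] = RegulatoryParams.from_dict(d["params"])
        if d.get("energy"):
            d["energy"] = EnergyModel.from_dict(d["energy"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_csv(frame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.10g")
    return path


def write_summary(summary: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
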