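"""Run configuration: every tunable of the pipeline in one serializable object.

Defaults follow the published protocol: dielectrics 1/4/8/8/80
(reference, membrane core, headgroups, protein, solvent), two-pass grid
focusing at 1.5 then 0.5 Å, 0.15 M ionic strength, explicit-ion cutoffs
3 Å (monovalent) and 6 Å (divalent), 2 Å headgroup shells, relevant pH
7.4 (closed) and 5.5 (open/desensitized), activation pH 6.0 and SSD pH
6.8 for protonation fractions, temperature 310 K.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .constants import PhysicalConstants
from .pka_engine import SolverSettings


@dataclass
class RunConfig:
    temperature: float = 310.0
    ionic_strength: float = 0.15
    region_values: dict = field(
        default_factory=lambda: {
            "reference": 1.0,
            "membrane_core": 4.0,
            "headgroups": 8.0,
            "protein": 8.0,
            "solvent": 80.0,
        }
    )
    coarse_spacing: float = 1.5
    fine_spacing: float = 0.5
    padding: float = 10.0
    focus_half_extent: float = 8.0
    solver_tol: float = 1.0e-6
    solver_maxiter: int = 10000
    headgroup_thickness: float = 2.0
    ion_thresholds: dict = field(default_factory=lambda: {1: 3.0, 2: 6.0})
    relevant_ph: dict = field(
        default_factory=lambda: {"closed": 7.4, "open": 5.5, "desensitized": 5.5}
    )
    ph_conditions: dict = field(
        default_factory=lambda: {"closed": 7.4, "activation": 6.0, "ssd": 6.8}
    )
    driver_threshold: float = 0.15
    range_bounds: tuple = (5.0, 8.0)
    max_rounds: int = 10
    update_mode: str = "all"
    seed: int = 0

    def constants(self) -> PhysicalConstants:
        return PhysicalConstants(
            temperature=self.temperature, ionic_strength=self.ionic_strength
        )

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(
            coarse_spacing=self.coarse_spacing,
            fine_spacing=self.fine_spacing,
            padding=self.padding,
            focus_half_extent=self.focus_half_extent,
            region_values=dict(self.region_values),
            tol=self.solver_tol,
            maxiter=self.solver_maxiter,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["range_bounds"] = list(self.range_bounds)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ion_thresholds" in data:
            data = dict(data)
            data["ion_thresholds"] = {int(k): float(v) for k, v in data["ion_thresholds"].items()}
        if "range_bounds" in data:
            data["range_bounds"] = tuple(data["range_bounds"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
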