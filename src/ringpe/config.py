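"""Run configuration: YAML serialisation, presets and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import units
from .dynamics import IntegratorSpec
from .forcefield import ForceFieldParams
from .units import SolutionSpec


class ConfigError(ValueError):
    """Configuration validation failure; message names the offending field."""


@dataclass(frozen=True)
class SimulationConfig:
    """One state point of the phase diagram plus the run protocol."""

    c_s: float = 1.78e-3
    bending: float = 0.0
    n_monomer: int = 200
    n_counterion: int | None = None  # defaults to n_monomer (neutrality)
    box_length: float = 150.0
    sigma_angstrom: float = units.DEFAULT_SIGMA_ANGSTROM
    bjerrum: float = units.DEFAULT_BJERRUM
    k_bond: float = 500.0
    r0: float = 1.12
    integrator: IntegratorSpec = field(default_factory=IntegratorSpec)

    def __post_init__(self) -> None:
        if self.c_s < 0:
            raise ConfigError("c_s: salt concentration must be nonnegative")
        if self.bending < 0:
            raise ConfigError("bending: bending energy b must be nonnegative")
        if self.n_monomer < 3:
            raise ConfigError("n_monomer: ring needs at least 3 beads")
        if self.box_length <= 0:
            raise ConfigError("box_length: must be positive")

    @property
    def counterions(self) -> int:
        return self.n_monomer if self.n_counterion is None else self.n_counterion

    def solution(self) -> SolutionSpec:
        return SolutionSpec(self.c_s, self.box_length, self.sigma_angstrom,
                            self.counterions, self.bjerrum)

    def forcefield(self) -> ForceFieldParams:
        sol = self.solution()
        return ForceFieldParams.for_solution(
            sol.lambda_d, self.box_length, bending=self.bending,
            k_bond=self.k_bond, r0=self.r0, bjerrum=self.bjerrum)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def checksum(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        integ = data.pop("integrator", {})
        try:
            spec = IntegratorSpec(**integ)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"integrator: {exc}") from exc
        try:
            return cls(integrator=spec, **data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


def full_scale_preset(c_s: float, bending: float, seed: int = 0) -> SimulationConfig:
    """The full study protocol: N = 200, L = 150, 1e7 + 1e7 steps, 10 runs."""
    return SimulationConfig(
        c_s=c_s, bending=bending,
        integrator=IntegratorSpec(seed=seed, n_equil=10_000_000,
                                  n_prod=10_000_000, dump_every=10_000,
                                  n_runs=10))


def desk_scale_preset(c_s: float, bending: float, seed: int = 0,
                      n_monomer: int = 50, box_length: float = 75.0,
                      n_equil: int = 400_000, n_prod: int = 200_000,
                      dump_every: int = 20_000, n_runs: int = 3) -> SimulationConfig:
    """Reduced protocol for a single workstation CPU."""
    return SimulationConfig(
        c_s=c_s, bending=bending, n_monomer=n_monomer, box_length=box_length,
        integrator=IntegratorSpec(seed=seed, n_equil=n_equil, n_prod=n_prod,
                                  dump_every=dump_every, n_runs=n_runs))


@dataclass
class RunManifest:
    """Enough provenance to re-run any stage bit-identically."""

    config_checksum: str
    seeds: list[int]
    outputs: dict
    version: str = "0.1.0"

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
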