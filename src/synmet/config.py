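"""Experiment configuration: schema, validation and loading.

Configs are flat YAML documents.  Unknown keys are rejected with a
suggestion, and every random draw is seeded explicitly — no wall-clock
seeding anywhere in the pipeline.
"""

from __future__ import annotations

import difflib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .universe import UniverseConfig

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one sampling-and-regression campaign."""

    universe: dict | str = field(default_factory=dict)  # UniverseConfig kwargs or path
    N_values: list = field(default_factory=lambda: [1])
    B_values: list = field(default_factory=lambda: [1])
    R_values: list = field(default_factory=list)
    uptake_bound: float = 10.0
    biomass_mode: str = "isostoichiometric"
    mode: str = "minimal"  # minimal | mcmc
    replicates: int = 5
    burn_in_factor: int = 5
    thinning_factor: int = 2
    mcmc_samples_per_start: int = 5
    seed: int = 0
    outdir: str = "synmet_run"

    def validate(self) -> "ExperimentConfig":
        if self.mode not in ("minimal", "mcmc"):
            raise ConfigError(f"mode must be 'minimal' or 'mcmc', got {self.mode!r}")
        if self.biomass_mode not in ("weighted", "isostoichiometric"):
            raise ConfigError(f"unknown biomass_mode {self.biomass_mode!r}")
        if self.mode == "mcmc" and not self.R_values:
            raise ConfigError("mcmc mode requires R_values")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.uptake_bound <= 0:
            raise ConfigError("uptake_bound must be positive")
        if isinstance(self.universe, dict):
            unknown = set(self.universe) - {f.name for f in fields(UniverseConfig)}
            if unknown:
                raise ConfigError(f"unknown universe keys: {sorted(unknown)}")
            UniverseConfig(**self.universe).validate()
        return self

    def universe_config(self) -> UniverseConfig:
        if not isinstance(self.universe, dict):
            raise ConfigError("universe is a path, not inline parameters")
        return UniverseConfig(**self.universe)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML config; unknown keys get a suggestion."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = [f.name for f in fields(ExperimentConfig)]
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ConfigError(f"{path}: unknown key {key!r}{suggestion}")
    return ExperimentConfig(**raw).validate()


def save_config(cfg: ExperimentConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
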