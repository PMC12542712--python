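"""Configuration objects for the simulation, sampler and pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Ground-truth parameters for the synthetic two-stage survey.

    The generator emulates an NFHS-style design: states contain districts,
    districts contain clusters (the primary sampling units), clusters
    contain individuals. ``beta0`` is the log-odds intercept per wave;
    ``sigma2_u/v/f`` are the cluster / district / state random-intercept
    variances on the log-odds scale.
    """

    n_states: int = 15
    districts_per_state: int = 8
    clusters_per_district: int = 10
    mean_persons_per_cluster: int = 30
    beta0: tuple[float, float] = (-2.2, -2.0)
    sigma2_u: float = 0.30
    sigma2_v: float = 0.20
    sigma2_f: float = 0.10
    biomarker_mode: str = "binary"  # "binary" | "biomarker"
    outcome: str = "hypertension"  # which biomarker family is calibrated
    sex: str = "female"  # stratum label carried through the pipeline
    missing_rate: float = 0.0
    split_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_states", "districts_per_state", "clusters_per_district",
                     "mean_persons_per_cluster"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("sigma2_u", "sigma2_v", "sigma2_f"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("missing_rate", "split_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.biomarker_mode not in ("binary", "biomarker"):
            raise ConfigurationError(f"unknown biomarker_mode {self.biomarker_mode!r}")
        if self.outcome not in ("hypertension", "diabetes"):
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if self.sex not in ("female", "male"):
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if isinstance(self.beta0, (int, float)):
            self.beta0 = (float(self.beta0), float(self.beta0))
        else:
            self.beta0 = tuple(float(b) for b in self.beta0)  # type: ignore[assignment]
            if len(self.beta0) != 2:
                raise ConfigurationError("beta0 must be a scalar or a (wave1, wave2) pair")


@dataclass
class PriorSpec:
    """Priors for the hierarchical logistic fit.

    Flat (improper) prior on the intercept; Inv-Gamma(a, b) on each variance
    component. The 0.001/0.001 default mirrors the conventional diffuse
    default of multilevel MCMC software.
    """

    variance_a: float = 0.001
    variance_b: float = 0.001

    def __post_init__(self) -> None:
        if self.variance_a <= 0 or self.variance_b <= 0:
            raise ConfigurationError("inverse-gamma hyperparameters must be positive")


@dataclass
class MCMCConfig:
    burn_in: int = 500
    monitoring: int = 5000
    thin: int = 1
    seed: int = 0
    prior: PriorSpec = field(default_factory=PriorSpec)
    init_mode: str = "pql"  # "pql" | "zeros" | "user"

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ConfigurationError("burn_in must be >= 0")
        if self.monitoring < 1:
            raise ConfigurationError("monitoring must be >= 1")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.init_mode not in ("pql", "zeros", "user"):
            raise ConfigurationError(f"unknown init_mode {self.init_mode!r}")
        if isinstance(self.prior, dict):
            self.prior = PriorSpec(**self.prior)

    @property
    def n_retained(self) -> int:
        return self.monitoring // self.thin


@dataclass
class PipelineConfig:
    """Full end-to-end run: simulate -> classify -> crosswalk -> fit -> estimate -> trends."""

    out_dir: str = "pipeline_out"
    outcomes: Sequence[str] = ("hypertension", "diabetes")
    sexes: Sequence[str] = ("female", "male")
    sim: SimConfig = field(default_factory=SimConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    bp_rule: str = "mean23"
    prediction_mode: str = "plugin"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if isinstance(self.mcmc, dict):
            self.mcmc = MCMCConfig(**self.mcmc)
        for o in self.outcomes:
            if o not in ("hypertension", "diabetes"):
                raise ConfigurationError(f"unknown outcome {o!r}")
        for s in self.sexes:
            if s not in ("female", "male"):
                raise ConfigurationError(f"unknown sex {s!r}")


def load_config(path: str | Path, kind: type = PipelineConfig):
    """Load a YAML key-value file into the given config dataclass."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return kind(**raw)


def dump_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
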