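"""Validated run configuration for the end-to-end pipeline.

The schema is strict: unknown keys are rejected and cross-field constraints
(e.g. background subtraction enabled without a background section) fail at
validation time, before any stage runs.
"""

from __future__ import annotations

import hashlib
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from dfmflow.synthetic_data.strains import DEFAULT_SEED

__all__ = [
    "BackgroundConfig",
    "GatingSection",
    "NoiseConfig",
    "RunConfig",
    "SampleConfig",
    "SimulateConfig",
    "config_hash",
    "demo_config",
    "load_config",
]

_VALID_PATTERNS = {"R", "Y", "B", "RY", "RB", "YB", "U"}


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    expr_gsd: float = 2.0
    autofluor: Optional[dict] = None  # channel key -> [median, gsd]
    doublet_rate: float = 0.02
    debris_rate: float = 0.03


class GatingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bacteria_mode: str = "density"
    density_fraction: float = 0.95
    polygon: Optional[list] = None
    singlet_fsc_min: float = 0.0
    singlet_ar_min: float = 0.4
    thresholds: Optional[dict] = None  # colour -> [channel key, FI]


class SampleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sample_id: str
    plant: str = ""
    timepoint: float = 0.0
    replicate: int = 0
    n_events: int = Field(10_000, ge=1)
    root_mass_g: Optional[float] = None
    analysed_volume_mL: Optional[float] = None
    acquisition_time_min: Optional[float] = None
    flow_rate_uL_min: Optional[float] = None
    dilution_factor: float = 1.0
    harvest_volume_mL: float = 25.0

    @model_validator(mode="after")
    def _one_volume_source(self):
        if (self.analysed_volume_mL is None) == (self.acquisition_time_min is None):
            raise ValueError(
                f"{self.sample_id}: provide exactly one of analysed_volume_mL "
                "or acquisition_time_min (with optional flow_rate_uL_min)"
            )
        return self


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    strains: dict  # strain id -> DFM pattern
    proportions: Optional[list] = None

    @model_validator(mode="after")
    def _check(self):
        if not self.strains:
            raise ValueError("at least one strain is required")
        bad = {p for p in self.strains.values() if p not in _VALID_PATTERNS}
        if bad:
            raise ValueError(f"unknown DFM pattern(s) {sorted(bad)}")
        if self.proportions is not None:
            if len(self.proportions) != len(self.strains):
                raise ValueError("proportions must match the number of strains")
            if abs(sum(self.proportions) - 1.0) > 1e-9:
                raise ValueError("proportions must sum to 1")
        return self


class BackgroundConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_events: int = Field(5_000, ge=1)
    replicates: int = Field(3, ge=1)
    root_mass_g: float = 0.5
    acquisition_time_min: float = 10.0


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = DEFAULT_SEED
    log_level: str = "INFO"
    simulate: SimulateConfig
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    gating: GatingSection = Field(default_factory=GatingSection)
    samples: list = Field(min_length=1)
    background: Optional[BackgroundConfig] = None
    subtract_background: bool = False

    @model_validator(mode="after")
    def _background_present(self):
        self.samples = [
            s if isinstance(s, SampleConfig) else SampleConfig(**s) for s in self.samples
        ]
        if self.subtract_background and self.background is None:
            raise ValueError(
                "subtract_background is enabled but no background section is "
                "configured"
            )
        if self.subtract_background:
            rootless = [s.sample_id for s in self.samples if s.root_mass_g is None]
            if rootless:
                raise ValueError(
                    f"background subtraction needs root_mass_g for samples {rootless}"
                )
        return self


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig(**data)


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of the fully validated configuration."""
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()


def demo_config(seed: int = DEFAULT_SEED) -> RunConfig:
    """Bundled six-strain community demo: two root samples plus background."""
    strains = {
        "OpAA2": "R",
        "AoDQS-4": "Y",
        "PfSBW25": "B",
        "EcAA4": "RY",
        "Rlv3841": "RB",
        "AxAT1": "YB",
    }
    samples = [
        SampleConfig(
            sample_id=f"pea_7dpi_rep{rep}",
            plant="pea",
            timepoint=7.0,
            replicate=rep,
            n_events=12_000,
            root_mass_g=0.5,
            acquisition_time_min=10.0,
        )
        for rep in range(1, 3)
    ]
    return RunConfig(
        seed=seed,
        simulate=SimulateConfig(strains=strains),
        samples=samples,
        background=BackgroundConfig(),
        subtract_background=True,
    )
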