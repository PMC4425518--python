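"""Experiment configuration, validation, and reproducible seeding.

A single YAML file configures morphology, channel densities, the
gap-junction layout scheme, solver settings and per-experiment
parameters; unknown keys are rejected.  One master seed spawns labelled
child streams (layout, density noise, protocol randomness, sensory
sampling) so each stochastic sub-experiment is independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from axonet import __version__
from axonet.channels import CHOSEN_MULTIPLIERS
from axonet.morphology import ConfigurationError

__all__ = [
    "MorphologyConfig",
    "ChannelConfig",
    "LayoutConfig",
    "SolverConfig",
    "PassiveConfig",
    "SensoryConfig",
    "ExperimentConfig",
    "SeedTree",
    "load_config",
    "save_config",
]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MorphologyConfig(_Block):
    n_neurons: int = Field(30, ge=1)
    soma_spacing: float = Field(10.0, gt=0)
    soma_area: float = Field(1000.0, gt=0)
    axon_diameter: float = Field(0.4, gt=0)
    axon_length: float = Field(1500.0, gt=0)
    hillock_proximal_diameter: float = Field(2.0, gt=0)
    hillock_section_length: float = Field(5.0, gt=0)


class InitialSegmentConfig(_Block):
    enabled: bool = True
    na_scale: float = Field(5.0, ge=0)
    k_scale: float = Field(0.5, ge=0)


class ChannelConfig(_Block):
    multipliers: dict[str, float] = Field(default_factory=lambda: dict(CHOSEN_MULTIPLIERS))
    noise_sd: float = Field(0.05, ge=0)
    lk_density: float = Field(0.125, gt=0)
    ca_internal: float = Field(1e-7, gt=0)
    ca_external: float = Field(1e-5, gt=0)
    initial_segment: InitialSegmentConfig = Field(default_factory=InitialSegmentConfig)

    @field_validator("multipliers")
    @classmethod
    def _nonnegative(cls, v):
        for kind, m in v.items():
            if m < 0:
                raise ValueError(f"multiplier for {kind!r} must be >= 0")
        return v


class LayoutConfig(_Block):
    variant: str = "density"
    probability_density: float = Field(0.015, ge=0)
    min_dist: float = Field(0.0, ge=0)
    max_dist: float = Field(50.0, gt=0)
    bin_width: float = Field(1.0, gt=0)
    max_neighbours: int = Field(6, ge=1)
    fixed_point: float = Field(30.0, ge=0)
    probability: float = Field(0.5, ge=0, le=1)
    resistance: float = Field(600.0, gt=0)


class SolverConfig(_Block):
    dt: float = Field(0.02, gt=0)
    settle: float = Field(20.0, ge=0)
    gj_mode: str = "semi"


class PassiveConfig(_Block):
    g_lk: float = Field(0.25, gt=0)
    n_runs: int = Field(50, ge=1)
    n_networks: int = Field(50, ge=1)
    current: float = -100.0


class SensoryConfig(_Block):
    population_size: int = Field(20, ge=1)
    peak_conductance: float | None = None  # nS; None -> calibrated at runtime
    tau_rise: float = Field(1.0, gt=0)
    tau_decay: float = Field(5.0, gt=0)
    stimulus_grid: list[float] = Field(
        default_factory=lambda: [80.0, 90.0, 95.0, 100.0, 105.0, 110.0]
    )
    replicates: int = Field(3, ge=1)


class ExperimentConfig(_Block):
    schema_version: int = 1
    morphology: MorphologyConfig = Field(default_factory=MorphologyConfig)
    channels: ChannelConfig = Field(default_factory=ChannelConfig)
    layout: LayoutConfig = Field(default_factory=LayoutConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    passive: PassiveConfig = Field(default_factory=PassiveConfig)
    sensory: SensoryConfig = Field(default_factory=SensoryConfig)

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class SeedTree:
    """Labelled child seeds derived from one master seed.

    Children are derived by hashing the label into the spawn key, so the
    stream for e.g. ``layout`` does not depend on whether ``noise`` was
    requested first.
    """

    def __init__(self, master: int):
        self.master = int(master)

    def seed(self, label: str, index: int = 0) -> int:
        digest = hashlib.sha256(f"{label}:{index}".encode()).digest()
        key = int.from_bytes(digest[:4], "little")
        ss = np.random.SeedSequence(self.master, spawn_key=(key,))
        return int(ss.generate_state(1)[0] % 2**31)

    def rng(self, label: str, index: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed(label, index))


def load_config(path: str | Path | None) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration.

    An empty or missing-content file yields the packaged defaults; schema
    violations raise with the offending key named.
    """
    if path is None:
        return ExperimentConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    try:
        return ExperimentConfig(**data)
    except Exception as exc:  # pydantic ValidationError carries key names
        raise ConfigurationError(f"invalid configuration {path}: {exc}") from exc


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def manifest(config: ExperimentConfig, master_seed: int, extra: dict | None = None) -> dict:
    out = {
        "software_version": __version__,
        "config_hash": config.content_hash(),
        "master_seed": int(master_seed),
        "config": config.model_dump(),
    }
    if extra:
        out.update(extra)
    return out
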