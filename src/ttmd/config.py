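"""Run configuration: validated schema for ramp, engine, scoring and
interaction-geometry thresholds, loadable from YAML."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ConfigurationError

__all__ = ["InteractionThresholds", "RunConfig", "load_config"]


class InteractionThresholds(BaseModel):
    """Geometric criteria for the eight fingerprint channels (Angstrom, deg).

    Defaults mirror widely used open-source interaction-fingerprint
    conventions so scores are comparable across pipelines.
    """

    hydrophobic_cutoff: float = 4.0
    f2f_centroid_cutoff: float = 4.5
    f2f_max_angle: float = 30.0
    e2f_centroid_cutoff: float = 5.5
    e2f_angle_range: tuple[float, float] = (60.0, 90.0)
    hbond_distance_cutoff: float = 3.5
    hbond_min_angle: float = 130.0  # D-H...A, only applied when hydrogens exist
    salt_bridge_cutoff: float = 4.0
    metal_cutoff: float = 2.8
    ring_planarity_tol: float = 0.1  # max out-of-plane deviation, Angstrom


class RampConfig(BaseModel):
    t_start: float = 300.0
    t_end: float = 450.0
    increment: float = 10.0
    window_length_ns: float = 10.0

    @model_validator(mode="after")
    def _check(self):
        if self.increment <= 0 or self.window_length_ns <= 0 or self.t_end < self.t_start:
            raise ValueError("ramp requires increment > 0, window_length > 0, t_end >= t_start")
        return self


class EngineConfig(BaseModel):
    kind: str = "synthetic"  # {synthetic, external}
    scenario: str = "stable"  # {stable, unbinder, partial_unfold}
    unbind_window: int = 3
    jitter_sigma0: float = 0.3
    frames_per_window: int = 100
    command: str | None = None  # external engine adapter command

    @model_validator(mode="after")
    def _check(self):
        if self.kind not in ("synthetic", "external"):
            raise ValueError(f"unknown engine kind {self.kind!r}")
        if self.scenario not in ("stable", "unbinder", "partial_unfold"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        return self


class ScoringConfig(BaseModel):
    stride: int = Field(default=1, ge=1)
    epsilon: float = Field(default=1e-4, gt=0)  # termination: mean IFP_CS >= -epsilon


class SystemConfig(BaseModel):
    pdb: str | None = None  # None: use the built-in toy complex
    params: str | None = None
    ligand: str = "LIG"
    water_cutoff: float = 4.5


class ReplicateConfig(BaseModel):
    count: int = Field(default=5, ge=1)
    master_seed: int = 1


class RunConfig(BaseModel):
    """Full run configuration; defaults follow the reference protocol
    (300 -> 450 K in 10 K / 10 ns windows, 5 replicates, MS cutoff 0.004)."""

    ramp: RampConfig = RampConfig()
    engine: EngineConfig = EngineConfig()
    scoring: ScoringConfig = ScoringConfig()
    interactions: InteractionThresholds = InteractionThresholds()
    system: SystemConfig = SystemConfig()
    replicates: ReplicateConfig = ReplicateConfig()
    ms_cutoff: float = 0.004  # K^-1; tight binder iff aggregate MS < cutoff
    backbone_threshold: float = 5.0  # Angstrom; fold-integrity advisory flag
    output_dir: str = "ttmd_out"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc
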