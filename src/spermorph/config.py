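"""Project-wide configuration: one validated, nested record.

The YAML dialect is plain ``section: {key: value}`` mapping onto the
pydantic models below.  Unknown keys are rejected with the offending key
named; every default equals the corresponding module-level default, so an
empty file yields the stock pipeline.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger("spermorph")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SynthSection(_Strict):
    width: int = 1200
    height: int = 900
    count_min: int = 15
    count_max: int = 30
    pixel_size_um: float = Field(0.25, gt=0)
    blur_sigma_px: float = Field(1.0, ge=0)
    noise_sd: float = Field(0.02, ge=0)
    overlap_prob: float = Field(0.0, ge=0.0, le=1.0)
    n_scenes: int = Field(2, ge=1)

    @model_validator(mode="after")
    def _check_counts(self):
        if not (0 <= self.count_min <= self.count_max):
            raise ValueError("count_min/count_max must form a non-empty range")
        return self


class SignalSection(_Strict):
    frequency_hz: float = Field(3.7, gt=0)
    fps: float = Field(60.0, gt=0)
    duration_s: float = Field(2.0, gt=0)
    baseline: float = 10.0
    amplitude: float = 2.0
    noise_sd: float = Field(0.1, ge=0)
    outlier_rate: float = Field(0.05, ge=0, lt=0.5)
    outlier_magnitude: float = 3.0


class NetworkSection(_Strict):
    mode: str = "gt"  # "gt" passthrough or "train"
    base_channels: int = Field(8, ge=1)
    pyramid_channels: int = Field(8, ge=1)
    base_stride: int = 1
    upsample: str = "bilinear"
    epochs: int = Field(100, ge=1)
    lr: float = Field(1e-4, gt=0)
    weight_decay: float = Field(1e-4, ge=0)
    lambda_inst: float = Field(1.0, ge=0)
    lambda_part: float = Field(1.0, ge=0)
    mask_threshold: float = Field(0.5, gt=0, lt=1)
    score_threshold: float = Field(0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self):
        if self.mode not in ("gt", "train"):
            raise ValueError("network.mode must be 'gt' or 'train'")
        if self.lambda_inst == 0 and self.lambda_part == 0:
            raise ValueError("loss weights cannot both be zero")
        return self


class MorphometrySection(_Strict):
    ellipticity_mode: str = "ratio"

    @model_validator(mode="after")
    def _check(self):
        if self.ellipticity_mode not in ("ratio", "eccentricity"):
            raise ValueError("ellipticity_mode must be 'ratio' or 'eccentricity'")
        return self


class EnhancementSection(_Strict):
    k: int = Field(2, ge=1)
    s: int = Field(2, ge=1)
    sigma: float = Field(0.7, gt=0)
    iqr_multiplier: float = 1.5
    min_separation: Optional[int] = None
    per_region_iqr: bool = False


class EvaluationSection(_Strict):
    include_background: bool = False


class SequenceSection(_Strict):
    """Frame-sequence simulation used by the end-to-end pipeline."""

    n_frames: int = Field(120, ge=4)
    fps: float = Field(60.0, gt=0)
    frequency_hz: float = Field(3.7, gt=0)
    modulation_depth: float = Field(0.15, ge=0, lt=1)
    jitter_px: float = Field(1.0, ge=0)
    max_link_displacement_px: float = Field(8.0, gt=0)


class ProjectConfig(_Strict):
    seed: int = 0
    output_dir: Path = Path("spermorph_out")
    log_level: str = "INFO"
    synth: SynthSection = Field(default_factory=SynthSection)
    signal: SignalSection = Field(default_factory=SignalSection)
    network: NetworkSection = Field(default_factory=NetworkSection)
    morphometry: MorphometrySection = Field(default_factory=MorphometrySection)
    enhancement: EnhancementSection = Field(default_factory=EnhancementSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)
    sequence: SequenceSection = Field(default_factory=SequenceSection)


def load_config(path: str | Path | None = None) -> ProjectConfig:
    """Load and validate a YAML config; an empty/absent file gives defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    cfg = ProjectConfig(**raw)
    logger.debug("loaded config: %s", cfg.model_dump())
    return cfg
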