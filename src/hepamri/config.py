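"""Validated pipeline configuration.

One config object carries every tunable the stages expose, with
defaults matching the study protocol, so a full run is reproducible
from a single JSON file plus a seed.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator


class ConfigError(ValueError):
    """Configuration invalid; message carries field-level details."""


class ScheduleConfig(BaseModel):
    fast_phase_duration: float = Field(30.0, gt=0, description="min")
    fast_frame_interval: float = Field(4.0, gt=0, description="s")
    slow_frame_interval: float = Field(10.0, gt=0, description="min")
    total_duration: float = Field(90.0, gt=0, description="min")
    injection_time: float = Field(2.0, gt=0, description="min")

    @model_validator(mode="after")
    def _check(self):
        if self.fast_phase_duration >= self.total_duration:
            raise ValueError("fast_phase_duration must be < total_duration")
        return self


class PipelineConfig(BaseModel):
    """Everything a simulate or analyze run needs."""

    schedule: ScheduleConfig = ScheduleConfig()
    r2_gate: float = Field(0.98, gt=0, le=1)
    threshold_lo: float = 0.0
    threshold_hi: float = 500.0
    lambda_partition: float = Field(0.9, gt=0, description="ml/g")
    normality_alpha: float = Field(0.05, gt=0, lt=1)
    seed: int = 0
    n_per_group: int = Field(7, ge=2)
    dce_noise_sd: float = Field(0.01, ge=0, description="fraction of A")
    ir_noise_frac: float = Field(0.01, ge=0)
    ir_shape: tuple[int, int] = (32, 32)
    input_dir: Path | None = None      # analyze mode: cohort directory
    output_dir: Path | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.threshold_lo >= self.threshold_hi:
            raise ValueError("threshold_lo must be < threshold_hi")
        return self

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            return cls.model_validate(json.loads(Path(path).read_text()))
        except Exception as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def settings_record(self) -> dict:
        """Flat record of every setting, for the run log."""
        d = self.model_dump(mode="json")
        return d
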