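"""Pipeline configuration, validated with pydantic.

Every analysis choice that the method leaves open is surfaced here so a
results file always carries its provenance: DTW step pattern and window,
confidence gating for pose tracks, pitch band and statistic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator


class KinematicsConfig(BaseModel):
    conf_threshold: float = Field(0.3, ge=0.0, le=1.0)
    max_missing_fraction: float = Field(0.5, ge=0.0, le=1.0)
    smoothing_window: int = Field(0, ge=0)  # 0 = off
    per_speaker_scale: bool = False


class DtwConfig(BaseModel):
    step_pattern: Literal["symmetric1", "symmetric2"] = "symmetric2"
    window_type: Literal["none", "sakoe_chiba"] = "none"
    window_size: int = Field(10, ge=0)

    @property
    def band(self) -> Optional[int]:
        return self.window_size if self.window_type == "sakoe_chiba" else None


class ProsodyConfig(BaseModel):
    pitch_floor: float = Field(75.0, gt=0)
    pitch_ceiling: float = Field(300.0, gt=0)
    statistic: Literal["mean", "max"] = "mean"
    frame_step_ms: float = Field(10.0, gt=0)
    voicing_threshold: float = Field(0.45, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _ordered_band(self):
        if self.pitch_ceiling <= self.pitch_floor:
            raise ValueError("pitch_ceiling must exceed pitch_floor")
        return self


class PipelineConfig(BaseModel):
    kinematics: KinematicsConfig = Field(default_factory=KinematicsConfig)
    dtw: DtwConfig = Field(default_factory=DtwConfig)
    prosody: ProsodyConfig = Field(default_factory=ProsodyConfig)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)
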