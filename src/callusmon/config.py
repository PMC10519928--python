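"""Run configuration for the command-line pipeline."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator


class RunConfig(BaseModel):
    """Validated knobs shared by the CLI commands.

    Thresholds are kept inside documented ranges; flag overrides win over
    values loaded from a config file.
    """

    seed: int = 0
    n_animals: int = Field(8, ge=1)
    n_treads: int = Field(8, ge=1)
    gait_day_start: int = Field(7, ge=0)
    gait_day_end: int = Field(91, gt=0)
    sensor_sigma: float = Field(0.05, ge=0.0, le=0.5)
    hu_sigma: float = Field(2.0, ge=0.0, le=100.0)
    jitter: float = Field(0.0, ge=0.0, le=0.5)
    body_weight_kg: float = Field(60.0, gt=0.0)
    calibration_window: tuple[float, float] = (7.0, 14.0)
    censor_fraction: float = Field(0.02, ge=0.0, le=0.5)
    healthy_fraction: float = Field(0.425, gt=0.0, le=1.0)
    density_threshold: float = Field(0.15, ge=0.0, le=0.8)
    tv_margin_mm: float = Field(10.0, ge=0.0, le=50.0)
    ct_spacing_mm: float = Field(0.3, gt=0.0, le=2.0)
    simulate_ct: bool = True
    verbose: bool = False

    @field_validator("calibration_window")
    @classmethod
    def _window_ordered(cls, v):
        if not v[0] < v[1]:
            raise ValueError(f"calibration window must be ordered, got {v}")
        return v

    @classmethod
    def load(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a JSON or YAML file; keyword overrides win."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
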