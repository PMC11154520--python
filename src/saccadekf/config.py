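"""Validated run configuration (YAML-loadable, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, field_validator


class BandpassSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    low_hz: float = 0.5
    high_hz: float = 35.0
    notch_hz: float = 60.0
    notch_q: float = 30.0
    sg_polyorder: int = 5
    sg_framelen: int = 111
    fir_numtaps: int = 251
    zero_phase: bool = True


#: Default process-noise intensity per model, selected at the knee of the
#: responsiveness-vs-smoothing trade-off for microvolt-scale signals at
#: 250 Hz: below it the filter lags the saccadic transition (peak velocity
#: collapses), above it measurement noise passes through. For the kinematic
#: models q is the white acceleration (CVM, (µV/s²)²) or jerk (CAM/LR,
#: (µV/s³)²) variance driving the integrator chain; for BM it is the
#: per-step random-walk variance (µV²).
DEFAULT_Q = {"bm": 50.0, "cvm": 3e8, "cam": 3e10, "lr": 3e10, "bp": 0.0}


class RunConfig(BaseModel):
    """Everything a pipeline run needs; see the CLI ``run`` subcommand."""

    model_config = ConfigDict(extra="forbid")

    model: Literal["bp", "bm", "cvm", "cam", "lr"] = "cvm"
    q: Optional[float] = None  # None → DEFAULT_Q[model]
    r: Optional[float] = None  # None → estimate from calibration trials
    fs: float = 250.0
    q_structure: Literal["white_noise", "diagonal"] = "white_noise"
    lr_constants: Optional[Tuple[float, float, float, float]] = None
    bandpass: BandpassSettings = BandpassSettings()
    calibration_threshold: float = 0.8
    iqr_multiplier: float = 1.5
    detrend_order: int = 1
    seed: int = 0
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"

    @field_validator("iqr_multiplier")
    @classmethod
    def _positive_multiplier(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("iqr_multiplier must be positive")
        return v

    @field_validator("q")
    @classmethod
    def _nonnegative_q(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v < 0:
            raise ValueError("q must be >= 0")
        return v

    @property
    def q_resolved(self) -> float:
        return self.q if self.q is not None else DEFAULT_Q[self.model]


def load_config(path) -> RunConfig:
    """Load and validate a YAML config file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)
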