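"""Validated run configuration (pydantic models, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_trials: int = Field(3, ge=1)
    n_reps: int = Field(3, ge=1)
    amplitude: float = Field(45.0, gt=0)
    diagonal_bias: float = Field(0.15, ge=0)
    noise_snr_db: float | None = 20.0
    spillover: float = Field(0.0, ge=0)
    j_wrist_true: int = Field(4, ge=1)
    j_grip_true: int = Field(1, ge=1)


class FilterConfig(_Strict):
    cutoff: float = Field(5.0, gt=0)
    order: int = Field(2, ge=1)
    zero_phase: bool = True
    target_rate: float = Field(74.0, gt=0)


class HALSOptions(_Strict):
    max_sweeps: int = Field(500, ge=1)
    tol: float = Field(1e-8, gt=0)
    n_restarts: int = Field(10, ge=1)


class ModelConfig(_Strict):
    strategy: str = Field("slrm2", pattern="^slrm[12]$")
    j_wrist: int = Field(4, ge=1)
    j_grip: int = Field(1, ge=1)
    include_grip_regressor: bool = True


class CVConfig(_Strict):
    train_condition: str = "comfortable_max"
    grip_train_condition: str = "grip_only"


class RunConfig(_Strict):
    """Everything one end-to-end run needs, under a single global seed."""

    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    filter: FilterConfig = FilterConfig()
    hals: HALSOptions = HALSOptions()
    model: ModelConfig = ModelConfig()
    cv: CVConfig = CVConfig()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
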