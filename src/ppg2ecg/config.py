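"""Run configuration schema and validation.

A single nested config drives the pipeline; values mirror the training
grid actually searched (gradient-penalty λ ∈ {4, 6, 30, 50}, learning rate ∈
{0.001, 0.002, 0.005}, batch ∈ {64, 128}) and the allowed analysis window
lengths {4, 8, 16, 32, 64, 96, 128, 160} s.  Validation errors are aggregated
with field paths before any computation starts.
"""

from __future__ import annotations

from pydantic import BaseModel, Field, field_validator

ALLOWED_WINDOWS = (4, 8, 16, 32, 64, 96, 128, 160)
GRID_LAMBDA = (4.0, 6.0, 30.0, 50.0)
GRID_LR = (0.001, 0.002, 0.005)
GRID_BATCH = (64, 128)


class SimulateSection(BaseModel):
    n_subjects: int = Field(2, ge=1)
    duration_s: float = Field(60.0, gt=0)
    artifact_level: float = Field(0.0, ge=0.0, le=1.0)
    ecg_fs: float = Field(130.0, ge=100.0)
    ppg_fs: float = Field(64.0, gt=0)


class PreprocessSection(BaseModel):
    target_fs: float = Field(130.0, gt=0)
    window_s: int = 4
    overlap_frac: float = Field(0.20, ge=0.0, lt=1.0)
    median_kernel: int = Field(5, ge=3)

    @field_validator("window_s")
    @classmethod
    def _window_allowed(cls, v):
        if v not in ALLOWED_WINDOWS:
            raise ValueError(f"window_s must be one of {ALLOWED_WINDOWS}")
        return v

    @field_validator("median_kernel")
    @classmethod
    def _odd(cls, v):
        if v % 2 == 0:
            raise ValueError("median_kernel must be odd")
        return v


class PretextSection(BaseModel):
    epochs: int = Field(3, ge=1)
    batch: int = Field(32, ge=1)
    lr: float = Field(1e-3, gt=0)
    n_folds: int = Field(2, ge=0)


class TrainSection(BaseModel):
    epochs: int = Field(4, ge=1)
    steps_per_epoch: int = Field(4, ge=1)
    batch: int = Field(16, ge=1)
    lr: float = Field(0.001, gt=0)
    betas: tuple[float, float] = (0.5, 0.9)
    gp_lambda: float = Field(30.0, ge=0.0)
    critic_steps_per_gen: int = Field(5, ge=1)
    recon_weight: float = Field(0.0, ge=0.0)
    reduced: bool = True           # desk-scale model widths

    @field_validator("betas")
    @classmethod
    def _betas_valid(cls, v):
        if not (0 < v[0] < 1 and 0 < v[1] < 1):
            raise ValueError(
                "Adam betas must lie strictly in (0, 1); printed grid values "
                ">= 1 are not valid exponential-decay rates")
        return v


class EvalSection(BaseModel):
    n_embed: int = Field(40, ge=4)
    n_perm: int = Field(200, ge=99)


class PipelineConfig(BaseModel):
    seed: int = 0
    simulate: SimulateSection = SimulateSection()
    preprocess: PreprocessSection = PreprocessSection()
    pretext: PretextSection = PretextSection()
    train: TrainSection = TrainSection()
    evaluation: EvalSection = EvalSection()


def validate_config(raw: dict) -> PipelineConfig:
    """Schema-check a raw mapping; pydantic reports field-addressed errors."""
    return PipelineConfig.model_validate(raw)
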