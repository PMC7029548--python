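"""Configuration models for the synthetic-cohort generator and the pipeline."""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: default class mixing (five latent SOFA-trajectory classes, ordered as
#: low-rising, rising, moderate-falling, high-falling, persistent-high)
DEFAULT_CLASS_PROPS = (0.2279, 0.0355, 0.5167, 0.1119, 0.1080)

#: default quadratic mean-trajectory coefficients (intercept, day, day^2) per
#: class: classes 1-2 rise over the first 10 ICU days, classes 3-5 fall from
#: increasingly high starting severity
DEFAULT_GROWTH_COEF = (
    (4.0, 0.20, 0.005),
    (7.0, 0.80, 0.010),
    (7.5, -0.80, 0.035),
    (11.0, -0.55, 0.020),
    (13.0, -0.25, 0.010),
)

DEFAULT_MISS_RATES = {
    "bun": 0.05,
    "albumin": 0.08,
    "hemoglobin": 0.04,
    "crp": 0.08,
    "neutrophils": 0.06,
    "lymphocytes": 0.06,
}


class SimConfig(BaseModel):
    """Generator settings for a synthetic sepsis cohort.

    The defaults encode the study conditions the analysis assumes: five
    latent classes with quadratic mean SOFA trajectories (two rising, three
    falling), mixing proportions near (0.23, 0.04, 0.52, 0.11, 0.11), an
    in-hospital death hazard whose acute-score coefficient steps down after
    ``attenuation_day`` while the antecedent coefficient is constant, and
    item-level MCAR missingness in the longitudinal labs.
    """

    model_config = ConfigDict(frozen=False)

    n_patients: int = Field(default=2000, ge=1)
    n_days: int = Field(default=10, ge=2)
    class_props: tuple[float, ...] = DEFAULT_CLASS_PROPS
    growth_coef: tuple[tuple[float, float, float], ...] = DEFAULT_GROWTH_COEF
    sigma_b: float = Field(default=1.2, ge=0.0)  # random-intercept SD (SOFA points)
    sigma_e: float = Field(default=1.5, gt=0.0)  # residual SD (SOFA points)
    #: (before, after attenuation_day) log-hazard slopes of the standardized acute score
    acute_effect: tuple[float, float] = (0.9, 0.1)
    #: (before, after) log-hazard slopes of the standardized antecedent score
    antecedent_effect: tuple[float, float] = (0.4, 0.4)
    baseline_hazard: float = Field(default=0.012, ge=0.0)  # deaths/day at score 0
    attenuation_day: float = Field(default=15.0, gt=0.0)
    #: ICU discharge-alive rate and post-ICU ward discharge rate (events/day)
    discharge_rate: float = Field(default=0.13, gt=0.0)
    ward_rate: float = Field(default=0.25, gt=0.0)
    #: max per-day upward drift of the urea:creatinine ratio for long-stayers
    ucr_drift: float = 0.8
    miss_rates: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_MISS_RATES))
    seed: int = 0

    @field_validator("class_props")
    @classmethod
    def _simplex(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        arr = np.asarray(v, dtype=float)
        if np.any(arr < 0):
            raise ValueError("class proportions must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError(f"class proportions must sum to 1, got {arr.sum()!r}")
        return v

    @field_validator("miss_rates")
    @classmethod
    def _rates(cls, v: dict[str, float]) -> dict[str, float]:
        for k, r in v.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"missingness rate for {k!r} must be in [0, 1], got {r}")
        return v

    @model_validator(mode="after")
    def _shapes(self) -> "SimConfig":
        if len(self.growth_coef) != len(self.class_props):
            raise ValueError("growth_coef must have one (b0, b1, b2) row per class")
        return self

    @property
    def n_classes(self) -> int:
        return len(self.class_props)


class PipelineConfig(BaseModel):
    """End-to-end pipeline settings (simulate -> ... -> signatures)."""

    sim: Optional[SimConfig] = None  # None = load user-supplied CSVs
    cohort_csv: Optional[str] = None
    panel_csv: Optional[str] = None
    seed: int = 0
    horizon: int = Field(default=28, ge=1)
    iters: int = Field(default=100, ge=1)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    gmax: int = Field(default=6, ge=1)
    min_class_n: int = Field(default=500, ge=1)
    n_starts: int = Field(default=4, ge=1)
    run_mixture: bool = True
    run_transition: bool = True
    run_survival: bool = True
    run_signatures: bool = True

    @model_validator(mode="after")
    def _inputs(self) -> "PipelineConfig":
        if self.sim is None and (self.cohort_csv is None or self.panel_csv is None):
            raise ValueError("either sim config or cohort_csv+panel_csv must be given")
        return self
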