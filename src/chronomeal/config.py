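"""Validated configuration objects for the generator and the pipeline.

All defaults encode the study conditions the package emulates: the
marginal distributions of the descriptive table of the source cohort
(118 young adults, 82 women) and the male-only planted standardized
slopes of weekly eating window (-0.605) and midsleep-to-first-intake
(+0.485) on log10 HOMA-IR.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, model_validator

MeanSD = Tuple[float, float]


class SexMarginals(BaseModel):
    """Per-sex (mean, SD) pairs for participant-level marginals.

    Lipid and HOMA-IR marginals are parameterized on the log10 scale
    because the analysis log-transforms them; SDs for skewed printed
    medians/IQRs were converted as IQR/1.349.
    """

    age_yr: MeanSD
    height_cm: MeanSD
    bmi: MeanSD
    fat_pct: MeanSD
    lean_mass_kg: MeanSD
    vat_g: MeanSD
    waist_cm: MeanSD
    sbp: MeanSD
    dbp: MeanSD
    glucose: MeanSD
    log10_triglycerides: MeanSD
    total_chol: MeanSD
    hdl: MeanSD
    log10_homa_ir: MeanSD
    eating_window_h: MeanSD
    med_diet_score: MeanSD
    light_pa_min: MeanSD

    @model_validator(mode="after")
    def _nonnegative_sds(self):
        for name, (_, sd) in self.__dict__.items():
            if sd < 0:
                raise ValueError(f"{name}: SD must be >= 0, got {sd}")
        return self


MEN_MARGINALS = SexMarginals(
    age_yr=(22.5, 2.3),
    height_cm=(176.3, 6.4),
    bmi=(27.4, 5.4),
    fat_pct=(31.1, 7.7),
    lean_mass_kg=(53.7, 7.5),
    vat_g=(446.7, 188.7),
    waist_cm=(91.4, 16.4),
    sbp=(126.0, 12.5),
    dbp=(73.0, 10.1),
    glucose=(89.5, 10.9),
    log10_triglycerides=(1.869, 0.195),
    total_chol=(155.0, 25.8),
    hdl=(46.5, 8.7),
    log10_homa_ir=(0.204, 0.236),
    eating_window_h=(12.0, 1.70),
    med_diet_score=(30.0, 6.0),
    light_pa_min=(120.0, 40.0),
)

WOMEN_MARGINALS = SexMarginals(
    age_yr=(22.1, 2.1),
    height_cm=(164.5, 6.7),
    bmi=(24.1, 3.9),
    fat_pct=(38.6, 5.9),
    lean_mass_kg=(36.6, 5.0),
    vat_g=(304.3, 171.2),
    waist_cm=(76.3, 10.9),
    sbp=(111.8, 9.6),
    dbp=(69.7, 6.6),
    glucose=(86.0, 5.2),
    log10_triglycerides=(1.833, 0.175),
    total_chol=(164.0, 30.0),
    hdl=(53.0, 11.5),
    log10_homa_ir=(0.176, 0.208),
    eating_window_h=(12.2, 1.40),
    med_diet_score=(32.0, 6.0),
    light_pa_min=(130.0, 40.0),
)


class CohortConfig(BaseModel):
    """Configuration of the synthetic cohort generator."""

    n_participants: int = Field(default=118, ge=2)
    fraction_women: float = Field(default=82 / 118, ge=0.0, le=1.0)
    seed: int = 0

    # planted male-only standardized slopes on log10 HOMA-IR
    effect_beta_window_homa_men: float = -0.605
    effect_beta_msp2first_homa_men: float = 0.485

    # weekly chronobiology anchors (clock h / h)
    midsleep_week_mean_h: float = 5.07  # 05:04
    midsleep_week_sd_h: float = Field(default=1.08, ge=0)
    sleep_duration_mean_h: float = 7.85
    sleep_duration_sd_h: float = Field(default=1.2, ge=0)
    social_jetlag_mean_h: float = 1.42
    social_jetlag_sd_h: float = Field(default=1.15, ge=0)
    msp_to_first_mean_h: float = 4.87
    msp_to_first_sd_h: float = Field(default=1.40, ge=0)
    eating_jetlag_mean_h: float = 1.20
    eating_jetlag_sd_h: float = Field(default=1.10, ge=0)

    # within-person realization noise
    daily_meal_jitter_sd_h: float = Field(default=0.30, ge=0)
    nightly_midsleep_jitter_sd_h: float = Field(default=0.35, ge=0)
    nightly_duration_jitter_sd_h: float = Field(default=0.50, ge=0)
    visit_bp_jitter_sd: float = Field(default=4.0, ge=0)
    wear_hours_mean: float = 22.5
    wear_hours_sd: float = Field(default=1.5, ge=0)

    # meals
    meal_kcal_mean: float = 600.0
    meal_kcal_sd: float = Field(default=180.0, ge=0)
    min_meals_per_day: int = Field(default=3, ge=1)
    max_meals_per_day: int = Field(default=5, ge=1)
    breakfast_skip_prob: float = Field(default=0.10, ge=0.0, le=1.0)

    # dual-entry emulation (percent CV between the two dietician entries)
    dual_entry_cv_sd: float = Field(default=2.5, ge=0)

    men: SexMarginals = MEN_MARGINALS
    women: SexMarginals = WOMEN_MARGINALS

    @model_validator(mode="after")
    def _check(self):
        b1 = self.effect_beta_window_homa_men
        b2 = self.effect_beta_msp2first_homa_men
        if b1 * b1 + b2 * b2 > 1.0:
            raise ValueError(
                "effect_beta_window_homa_men and effect_beta_msp2first_homa_men: "
                f"squared planted slopes sum to {b1 * b1 + b2 * b2:.3f} > 1; "
                "standardized slopes on independent exposures cannot exceed unit variance"
            )
        if self.max_meals_per_day < self.min_meals_per_day:
            raise ValueError("max_meals_per_day: must be >= min_meals_per_day")
        return self


class Conventions(BaseModel):
    """Analysis conventions left open by the study report; every choice
    here is a documented default, not a claim about the original study."""

    week_weight_working: float = 5.0 / 7.0
    week_weight_nonworking: float = 2.0 / 7.0
    breakfast_cutoff_h: float = 11.0
    breakfast_min_kcal: float = 50.0
    caloric_threshold_kcal: float = 0.0  # energy > threshold counts as caloric
    rollover_hour: float = 4.0
    cv_threshold_pct: float = 5.0
    multiplicity: Literal["bh", "hochberg"] = "bh"
    risk_bp_variable: Literal["mean_bp", "sbp"] = "mean_bp"
    restandardize_risk_score: bool = False
    shapiro_alpha: float = 0.05

    @model_validator(mode="after")
    def _weights(self):
        total = self.week_weight_working + self.week_weight_nonworking
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"week weights must sum to 1, got {total}")
        return self


class PipelineConfig(BaseModel):
    """Top-level pipeline configuration: real input files XOR a simulate block."""

    recalls_path: Optional[Path] = None
    sleep_path: Optional[Path] = None
    participants_path: Optional[Path] = None
    simulate: Optional[CohortConfig] = None
    dual_entries: bool = True  # when simulating, exercise the reconciliation rule
    conventions: Conventions = Conventions()
    output_dir: Path = Path("results")
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _exactly_one_source(self):
        paths = [self.recalls_path, self.sleep_path, self.participants_path]
        have_paths = all(p is not None for p in paths)
        any_paths = any(p is not None for p in paths)
        if self.simulate is not None and any_paths:
            raise ValueError("provide input paths or a simulate block, not both")
        if self.simulate is None and not have_paths:
            raise ValueError(
                "recalls_path, sleep_path and participants_path are all required "
                "when no simulate block is given"
            )
        return self


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a YAML (or JSON, a YAML subset) pipeline configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
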