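"""Anthropometric indices, blood-pressure and biochemical markers, and
the sex-stratified composite cardiometabolic risk Z-score.

The risk score standardizes waist circumference, blood pressure (mean BP
by default), fasting glucose, HDL-C (sign-flipped so higher = worse) and
triglycerides within each sex stratum (sample SD, n-1), and averages the
five Z-values.  Complete cases only; incomplete rows get a missing
score.  Within each stratum the score has mean 0 by construction; being
a mean of imperfectly correlated Z-scores its SD is below 1 unless the
optional re-standardization switch is used (off by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError, StratumError

RISK_COMPONENTS = ("waist_cm", "mean_bp", "glucose", "hdl", "triglycerides")
FRIEDEWALD_TG_LIMIT = 400.0


def bmi(weight_kg, height_cm):
    """Body-mass index: weight (kg) / height (m) squared."""
    return np.asarray(weight_kg, dtype=float) / (np.asarray(height_cm, dtype=float) / 100.0) ** 2


def lean_mass_index(lean_mass_kg, height_cm):
    """Lean mass (kg) divided by height (m) squared."""
    return np.asarray(lean_mass_kg, dtype=float) / (np.asarray(height_cm, dtype=float) / 100.0) ** 2


def mean_blood_pressure(sbp, dbp):
    """Mean BP = DBP + (SBP - DBP) / 3, mmHg."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(sbp < dbp):
        raise InputError("systolic blood pressure below diastolic")
    out = dbp + (sbp - dbp) / 3.0
    return float(out) if out.ndim == 0 else out


def homa_ir(glucose_mg_dl, insulin_uiu_ml):
    """HOMA-IR = fasting glucose (mg/dl) x fasting insulin (uIU/ml) / 405."""
    glucose = np.asarray(glucose_mg_dl, dtype=float)
    insulin = np.asarray(insulin_uiu_ml, dtype=float)
    if np.any(glucose <= 0):
        raise InputError("fasting glucose must be positive")
    out = glucose * insulin / 405.0
    return float(out) if out.ndim == 0 else out


def ldl_friedewald(total_chol, hdl, triglycerides):
    """LDL-C estimate: TC - HDL - TG/5 (mg/dl), missing when TG >= 400."""
    tc = np.asarray(total_chol, dtype=float)
    h = np.asarray(hdl, dtype=float)
    tg = np.asarray(triglycerides, dtype=float)
    out = np.where(tg >= FRIEDEWALD_TG_LIMIT, np.nan, tc - h - tg / 5.0)
    return float(out) if out.ndim == 0 else out


def risk_z_score(
    panel: pd.DataFrame,
    stratify_by_sex: bool = True,
    bp_variable: str = "mean_bp",
    restandardize: bool = False,
) -> pd.DataFrame:
    """Composite cardiometabolic risk Z-score per participant.

    Returns a copy of ``panel`` with ``z_<component>`` columns and
    ``risk_z``.  Standardization is within sex stratum (or overall when
    ``stratify_by_sex`` is false); the HDL Z is multiplied by -1.
    ``restandardize`` optionally rescales the final score to unit
    stratum SD.
    """
    components = [bp_variable if c == "mean_bp" else c for c in RISK_COMPONENTS]
    missing = [c for c in components if c not in panel.columns]
    if missing:
        raise InputError(f"risk score components missing from panel: {', '.join(missing)}")
    out = panel.copy()
    group_key = out["sex"] if stratify_by_sex else pd.Series("all", index=out.index)
    complete = out[components].notna().all(axis=1)

    for stratum, idx in out.index.groupby(group_key).items():
        rows = out.loc[idx]
        ok = complete.loc[idx]
        n_complete = int(ok.sum())
        if n_complete < 2:
            raise StratumError(
                f"stratum {stratum!r}: {n_complete} complete case(s); need >= 2"
            )
        sub = rows.loc[ok, components]
        mean = sub.mean()
        sd = sub.std(ddof=1)
        if (sd == 0).any():
            zero = list(sd.index[sd == 0])
            raise StratumError(f"stratum {stratum!r}: zero variance in {zero}")
        z = (sub - mean) / sd
        z["hdl"] = -z["hdl"]  # higher HDL = lower risk
        score = z.mean(axis=1)
        if restandardize:
            score = (score - score.mean()) / score.std(ddof=1)
        for comp in components:
            out.loc[sub.index, f"z_{comp}"] = z[comp]
        out.loc[sub.index, "risk_z"] = score
    if "risk_z" not in out.columns:
        out["risk_z"] = np.nan
    out.loc[~complete, "risk_z"] = np.nan
    return out


def derive_panel(
    participants: pd.DataFrame,
    bp_variable: str = "mean_bp",
    restandardize_risk: bool = False,
) -> pd.DataFrame:
    """Derive all marker columns from a raw participant table.

    Averages the three visit BP readings, then appends BMI, lean mass
    index (when lean mass is supplied), mean BP, HOMA-IR, Friedewald
    LDL (with a ``ldl_qc_flag`` for TG >= 400) and the sex-stratified
    risk Z-score.  Input columns are never overwritten.
    """
    out = participants.copy()
    sbp_cols = [c for c in out.columns if c.startswith("sbp_visit")]
    dbp_cols = [c for c in out.columns if c.startswith("dbp_visit")]
    if sbp_cols and dbp_cols:
        out["sbp"] = out[sbp_cols].mean(axis=1)
        out["dbp"] = out[dbp_cols].mean(axis=1)
    out["bmi"] = bmi(out["weight_kg"], out["height_cm"])
    if "lean_mass_kg" in out.columns:
        out["lean_mass_index"] = lean_mass_index(out["lean_mass_kg"], out["height_cm"])
    out["mean_bp"] = mean_blood_pressure(out["sbp"], out["dbp"])
    out["homa_ir"] = homa_ir(out["glucose"], out["insulin"])
    out["ldl"] = ldl_friedewald(out["total_chol"], out["hdl"], out["triglycerides"])
    out["ldl_qc_flag"] = out["triglycerides"] >= FRIEDEWALD_TG_LIMIT
    return risk_z_score(
        out,
        stratify_by_sex=True,
        bp_variable=bp_variable,
        restandardize=restandardize_risk,
    )
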