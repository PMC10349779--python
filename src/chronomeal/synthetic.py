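"""Synthetic chrononutrition cohort with planted male-only effects.

The generator emulates a cross-sectional cohort of young adults in which
every participant contributes three 24-h dietary recalls (two working
days, one non-working day), seven consecutive actigraphy nights (five
working, two non-working) and a fasting cardiometabolic panel.  Marginal
distributions default to the descriptive table of the emulated study.

The design is latent-anchor based: each participant owns weekly latent
values (weekly midsleep point, sleep duration, social jetlag, eating
window, midsleep-to-first-intake gap, eating jetlag) and every night or
recall day realizes those anchors plus Gaussian jitter.  The weighted
5/7-2/7 weekly means recomputed downstream therefore estimate the
latents, which are stored as ``true_*`` columns and constitute the
planted truth.

In men, log10 HOMA-IR is generated as a linear model on the standardized
weekly eating window and midsleep-to-first-intake gap with configured
standardized slopes; the residual SD is chosen so total variance is the
configured marginal variance, which makes the planted slopes directly
recoverable by simple OLS.  In women both slopes are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig, SexMarginals
from .timeaxis import format_clock, mod24

BASE_DATE = np.datetime64("2016-10-03")  # a Monday
RECALL_DAY_OFFSETS = (7, 9, 13)  # two working days, one Sunday
RECALL_DAY_TYPES = ("working", "working", "non-working")
N_SLEEP_NIGHTS = 7
N_WORKING_NIGHTS = 5

_MIN_EVENT_KCAL = 80.0
_ROOT2 = float(np.sqrt(2.0))


@dataclass
class SyntheticCohort:
    """Generated cohort: three tables plus the planted-truth record.

    ``truth`` maps (stratum, exposure, outcome) to the planted
    standardized slope used during generation.
    """

    participants: pd.DataFrame
    recall_events: pd.DataFrame
    sleep_nights: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _draw(rng, n, mean, sd):
    return rng.normal(mean, sd, size=n)


def _per_sex(rng, is_man, men: SexMarginals, women: SexMarginals, key):
    n = is_man.size
    out = np.empty(n)
    m_mean, m_sd = getattr(men, key)
    w_mean, w_sd = getattr(women, key)
    out[is_man] = rng.normal(m_mean, m_sd, size=int(is_man.sum()))
    out[~is_man] = rng.normal(w_mean, w_sd, size=int((~is_man).sum()))
    return out


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    n_women = int(round(n * cfg.fraction_women))
    n_men = n - n_women
    sex = np.array(["man"] * n_men + ["woman"] * n_women)
    is_man = sex == "man"
    pid = np.array([f"P{i + 1:04d}" for i in range(n)])

    # --- participant-level biomarker marginals ------------------------------
    age = _per_sex(rng, is_man, cfg.men, cfg.women, "age_yr")
    height = _per_sex(rng, is_man, cfg.men, cfg.women, "height_cm")
    bmi = np.clip(_per_sex(rng, is_man, cfg.men, cfg.women, "bmi"), 16.0, 45.0)
    weight = bmi * (height / 100.0) ** 2
    fat_pct = np.clip(_per_sex(rng, is_man, cfg.men, cfg.women, "fat_pct"), 8.0, 60.0)
    lean = np.clip(_per_sex(rng, is_man, cfg.men, cfg.women, "lean_mass_kg"), 20.0, None)
    vat = np.clip(_per_sex(rng, is_man, cfg.men, cfg.women, "vat_g"), 30.0, None)
    waist = np.clip(_per_sex(rng, is_man, cfg.men, cfg.women, "waist_cm"), 55.0, None)
    sbp = _per_sex(rng, is_man, cfg.men, cfg.women, "sbp")
    dbp = _per_sex(rng, is_man, cfg.men, cfg.women, "dbp")
    dbp = np.minimum(dbp, sbp - 20.0)  # keep pulse pressure physiologic
    glucose = np.clip(_per_sex(rng, is_man, cfg.men, cfg.women, "glucose"), 60.0, None)
    trig = 10.0 ** _per_sex(rng, is_man, cfg.men, cfg.women, "log10_triglycerides")
    tchol = np.clip(_per_sex(rng, is_man, cfg.men, cfg.women, "total_chol"), 90.0, None)
    hdl = np.clip(_per_sex(rng, is_man, cfg.men, cfg.women, "hdl"), 20.0, None)
    med = _per_sex(rng, is_man, cfg.men, cfg.women, "med_diet_score")
    lpa = np.clip(_per_sex(rng, is_man, cfg.men, cfg.women, "light_pa_min"), 0.0, None)

    # --- weekly chronobiology latents ---------------------------------------
    msp_week = _draw(rng, n, cfg.midsleep_week_mean_h, cfg.midsleep_week_sd_h)
    msp_week = np.clip(msp_week, 1.0, 9.0)
    sjl = _draw(rng, n, cfg.social_jetlag_mean_h, cfg.social_jetlag_sd_h)
    dur = np.clip(_draw(rng, n, cfg.sleep_duration_mean_h, cfg.sleep_duration_sd_h), 5.0, 11.0)
    gap = np.clip(_draw(rng, n, cfg.msp_to_first_mean_h, cfg.msp_to_first_sd_h), 1.5, 10.0)
    window = np.clip(
        _per_sex(rng, is_man, cfg.men, cfg.women, "eating_window_h"), 7.0, 17.5
    )
    ejl = _draw(rng, n, cfg.eating_jetlag_mean_h, cfg.eating_jetlag_sd_h)

    # --- HOMA-IR with planted effects in men --------------------------------
    b1 = cfg.effect_beta_window_homa_men
    b2 = cfg.effect_beta_msp2first_homa_men
    resid_scale = float(np.sqrt(max(0.0, 1.0 - b1 * b1 - b2 * b2)))
    eps = rng.standard_normal(n)
    mw_mean, mw_sd = cfg.men.eating_window_h
    z_window = np.where(
        is_man,
        (window - mw_mean) / mw_sd,
        (window - cfg.women.eating_window_h[0]) / cfg.women.eating_window_h[1],
    )
    z_gap = (gap - cfg.msp_to_first_mean_h) / cfg.msp_to_first_sd_h
    mu_m, s_m = cfg.men.log10_homa_ir
    mu_w, s_w = cfg.women.log10_homa_ir
    log10_homa = np.where(
        is_man,
        mu_m + s_m * (b1 * z_window + b2 * z_gap + resid_scale * eps),
        mu_w + s_w * eps,
    )
    homa = 10.0 ** log10_homa
    insulin = homa * 405.0 / glucose  # HOMA-IR = glucose * insulin / 405

    bp_visits = {}
    for k in range(3):
        bp_visits[f"sbp_visit{k + 1}"] = sbp + rng.normal(0, cfg.visit_bp_jitter_sd, n)
        bp_visits[f"dbp_visit{k + 1}"] = dbp + rng.normal(0, cfg.visit_bp_jitter_sd, n)

    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "sex": sex,
            "age_yr": age,
            "height_cm": height,
            "weight_kg": weight,
            "fat_pct": fat_pct,
            "lean_mass_kg": lean,
            "vat_g": vat,
            "waist_cm": waist,
            **bp_visits,
            "glucose": glucose,
            "insulin": insulin,
            "triglycerides": trig,
            "total_chol": tchol,
            "hdl": hdl,
            "med_diet_score": med,
            "light_pa_min": lpa,
            "true_eating_window_h": window,
            "true_msp_to_first_h": gap,
            "true_midsleep_week_h": msp_week,
            "true_social_jetlag_h": sjl,
            "true_eating_jetlag_h": ejl,
            "true_log10_homa_ir": log10_homa,
        }
    ).round(4)

    sleep_nights = _generate_sleep(rng, cfg, pid, msp_week, sjl, dur)
    recall_events = _generate_recalls(rng, cfg, pid, msp_week, gap, window, ejl)

    truth = {
        ("men", "eating_window", "log10_homa_ir"): b1,
        ("men", "msp_to_first", "log10_homa_ir"): b2,
        ("women", "eating_window", "log10_homa_ir"): 0.0,
        ("women", "msp_to_first", "log10_homa_ir"): 0.0,
    }
    return SyntheticCohort(participants, recall_events, sleep_nights, truth)


def _generate_sleep(rng, cfg, pid, msp_week, sjl, dur):
    n = pid.size
    rows = []
    # stratum anchors chosen so the 5/7-2/7 weighted weekly mean equals the latent
    msp_working = msp_week - (2.0 / 7.0) * sjl
    for j in range(N_SLEEP_NIGHTS):
        working = j < N_WORKING_NIGHTS
        anchor = msp_working if working else msp_working + sjl
        msp_night = anchor + 24.0 + rng.normal(0, cfg.nightly_midsleep_jitter_sd_h, n)
        dur_night = np.clip(dur + rng.normal(0, cfg.nightly_duration_jitter_sd_h, n), 4.0, 12.0)
        onset = np.round((msp_night - dur_night / 2.0) * 60) / 60
        offset = np.round((msp_night + dur_night / 2.0) * 60) / 60
        wear = np.clip(rng.normal(cfg.wear_hours_mean, cfg.wear_hours_sd, n), 10.0, 24.0)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "date": np.repeat(BASE_DATE + j, n),
                    "day_type": "working" if working else "non-working",
                    "onset_axis_h": onset,
                    "offset_axis_h": offset,
                    "wear_hours": np.round(wear, 2),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["participant_id", "date"], kind="mergesort").reset_index(drop=True)


def _generate_recalls(rng, cfg, pid, msp_week, gap, window, ejl):
    n = pid.size
    jit = cfg.daily_meal_jitter_sd_h
    first_anchor = msp_week + gap  # within-day axis
    skip = rng.random(n) < cfg.breakfast_skip_prob
    skip_day = rng.integers(0, len(RECALL_DAY_OFFSETS), size=n)

    frames = []
    max_interior = cfg.max_meals_per_day - 2
    for d, (offset_days, day_type) in enumerate(zip(RECALL_DAY_OFFSETS, RECALL_DAY_TYPES)):
        shift = -(2.0 / 7.0) * ejl if day_type == "working" else (5.0 / 7.0) * ejl
        first = np.clip(first_anchor + shift + rng.normal(0, jit, n), 4.25, 20.0)
        w_day = np.clip(window + rng.normal(0, jit, n), 3.0, 27.6 - first)
        last = first + w_day
        m = rng.integers(cfg.min_meals_per_day, cfg.max_meals_per_day + 1, size=n)
        interior = np.sort(
            rng.uniform(first[:, None] + 0.5, last[:, None] - 0.5, size=(n, max(max_interior, 1))),
            axis=1,
        )
        slot_times = [first]
        for k in range(max_interior):
            slot_times.append(interior[:, k])
        slot_times.append(last)
        n_slots = len(slot_times)
        keep = np.zeros((n, n_slots), dtype=bool)
        keep[:, 0] = ~(skip & (skip_day == d))  # breakfast-skip deletion
        keep[:, -1] = True
        for k in range(max_interior):
            keep[:, 1 + k] = (k < m - 2)
        times = np.column_stack(slot_times)
        energy = np.clip(
            rng.normal(cfg.meal_kcal_mean, cfg.meal_kcal_sd, size=(n, n_slots)),
            _MIN_EVENT_KCAL,
            None,
        )
        idx_p, idx_s = np.nonzero(keep)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid[idx_p],
                    "date": np.repeat(BASE_DATE + offset_days, idx_p.size),
                    "day_type": day_type,
                    "axis_time": np.round(times[idx_p, idx_s] * 60) / 60,
                    "energy_kcal": np.round(energy[idx_p, idx_s], 2),
                    "meal_label": "",
                    "entry_id": "A",
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["clock_time"] = mod24(out["axis_time"].to_numpy())
    out["is_caloric"] = out["energy_kcal"] > 0
    out = out.sort_values(
        ["participant_id", "date", "axis_time"], kind="mergesort"
    ).reset_index(drop=True)
    return out[
        [
            "participant_id",
            "date",
            "day_type",
            "clock_time",
            "axis_time",
            "energy_kcal",
            "meal_label",
            "entry_id",
            "is_caloric",
        ]
    ]


def emit_dual_entries(cohort: SyntheticCohort, config: CohortConfig) -> pd.DataFrame:
    """Duplicate every recall day under two dietician entry IDs (A, B).

    Entry B rescales all event energies of the day by a common factor
    chosen so the daily-total coefficient of variation between A and B
    equals a draw from |N(0, dual_entry_cv_sd)| percent.  Days whose CV
    exceeds 5% additionally receive a near-exact third entry C, which
    the reconciliation rule is expected to pair with A.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    events = cohort.recall_events.copy()
    days = events.groupby(["participant_id", "date"], sort=True, observed=True).size()
    n_days = len(days)
    cv = np.abs(rng.normal(0.0, config.dual_entry_cv_sd, n_days))
    cv = np.minimum(cv, 60.0)
    sign = rng.choice([-1.0, 1.0], size=n_days)
    # CV(a, a(1+d)) = 100*|d|/(sqrt(2)*(1+d/2)); invert for d
    d = sign * (cv / 100.0) / (1.0 / _ROOT2 - sign * cv / 200.0)
    cv3 = np.abs(rng.normal(0.0, 0.5, n_days))
    d3 = (cv3 / 100.0) / (1.0 / _ROOT2 - cv3 / 200.0)

    key = pd.MultiIndex.from_frame(events[["participant_id", "date"]])
    day_index = pd.Series(np.arange(n_days), index=days.index)
    event_day = day_index.reindex(key).to_numpy()

    entry_b = events.copy()
    entry_b["energy_kcal"] = np.round(events["energy_kcal"].to_numpy() * (1.0 + d[event_day]), 2)
    entry_b["entry_id"] = "B"

    need_c = cv > 5.0
    mask_c = need_c[event_day]
    entry_c = events.loc[mask_c].copy()
    entry_c["energy_kcal"] = np.round(
        events.loc[mask_c, "energy_kcal"].to_numpy() * (1.0 + d3[event_day[mask_c]]), 2
    )
    entry_c["entry_id"] = "C"

    out = pd.concat([events, entry_b, entry_c], ignore_index=True)
    return out.sort_values(
        ["participant_id", "date", "entry_id", "axis_time"], kind="mergesort"
    ).reset_index(drop=True)


# --------------------------------------------------------------------------
# writers for the three downstream CSV schemas
# --------------------------------------------------------------------------

def write_recalls_csv(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out["time"] = [format_clock(t) for t in out["clock_time"]]
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[
        ["participant_id", "date", "day_type", "time", "energy_kcal", "meal_label", "entry_id"]
    ].to_csv(path, index=False, float_format="%.2f")


def write_sleep_csv(nights: pd.DataFrame, path: str | Path) -> None:
    out = nights.copy()
    out["onset"] = [format_clock(t) for t in out["onset_axis_h"]]
    out["offset"] = [format_clock(t) for t in out["offset_axis_h"]]
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[["participant_id", "date", "day_type", "onset", "offset", "wear_hours"]].to_csv(
        path, index=False, float_format="%.2f"
    )


def write_participants_csv(participants: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in participants.columns if not c.startswith("true_")]
    participants[cols].to_csv(path, index=False, float_format="%.4f")


def write_truth_csv(cohort: SyntheticCohort, path: str | Path) -> None:
    cols = ["participant_id", "sex"] + [
        c for c in cohort.participants.columns if c.startswith("true_")
    ]
    cohort.participants[cols].to_csv(path, index=False, float_format="%.6f")


def write_cohort(
    cohort: SyntheticCohort,
    outdir: str | Path,
    dual_entries: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write recalls/sleep/participants (+truth) CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "recalls": outdir / "recalls.csv",
        "sleep": outdir / "sleep.csv",
        "participants": outdir / "participants.csv",
        "truth": outdir / "truth.csv",
    }
    write_recalls_csv(
        dual_entries if dual_entries is not None else cohort.recall_events, paths["recalls"]
    )
    write_sleep_csv(cohort.sleep_nights, paths["sleep"])
    write_participants_csv(cohort.participants, paths["participants"])
    write_truth_csv(cohort, paths["truth"])
    return paths
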