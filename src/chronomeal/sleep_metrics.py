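"""Actigraphy validity filtering and weekly sleep variables.

Per-night sleep onset/offset come in as inputs (detection from raw
acceleration is upstream of this package).  Nights live on the
noon-anchored axis [12, 36) so that averaging across midnight is linear;
the weekly midsleep point is the 5/7-2/7 weighted mean of the working
and non-working stratum means, and social jetlag is the signed
non-working minus working midsleep difference.  Participants with more
than 4 days under 16 h of wear, or without any non-working (weekend)
night, fail the validity filter.  Daytime naps are ignored by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChronomealError, RowParseError, SchemaError
from .timeaxis import mod24, parse_clock, to_noon_axis

SLEEP_COLUMNS = ("participant_id", "date", "day_type", "onset", "offset", "wear_hours")

MIN_WEAR_HOURS = 16.0
MAX_LOW_WEAR_DAYS = 4


@dataclass
class WeeklySleepSummary:
    participant_id: str
    midsleep_week: float  # clock hours
    midsleep_working: float
    midsleep_nonworking: float
    sleep_duration_week: float
    social_jetlag: float  # signed hours
    valid: bool
    invalid_reason: str = ""


def read_sleep_table(path: str | Path) -> pd.DataFrame:
    """Read the per-night sleep CSV into a typed table on the noon axis."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SLEEP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    onset = np.empty(len(df))
    offset = np.empty(len(df))
    wear = np.empty(len(df))
    dates = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            onset[i] = to_noon_axis(parse_clock(row.onset))
            offset[i] = to_noon_axis(parse_clock(row.offset))
        except ValueError as exc:
            raise RowParseError(str(exc), line=line) from None
        if offset[i] <= onset[i]:
            offset[i] += 24.0
        if not 0 < offset[i] - onset[i] < 24:
            raise RowParseError(
                f"implausible night: onset {row.onset}, offset {row.offset}", line=line
            )
        try:
            wear[i] = float(row.wear_hours)
        except ValueError:
            raise RowParseError(f"unparseable wear_hours: {row.wear_hours!r}", line=line) from None
        try:
            dates.append(pd.Timestamp(row.date).date())
        except ValueError:
            raise RowParseError(f"unparseable date: {row.date!r}", line=line) from None
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].astype(str),
            "date": dates,
            "day_type": df["day_type"].astype(str),
            "onset_axis_h": onset,
            "offset_axis_h": offset,
            "wear_hours": wear,
        }
    )
    return out.sort_values(["participant_id", "date"], kind="mergesort").reset_index(drop=True)


def is_valid_actigraphy(nights: pd.DataFrame) -> tuple[bool, str]:
    """Validity filter for one participant's night collection.

    Invalid iff more than 4 days registered under 16 h of wear time, or
    no non-working day is present.  Returns (flag, reason).
    """
    if len(nights) == 0:
        return False, "no actigraphy nights recorded"
    low_wear = int((nights["wear_hours"] < MIN_WEAR_HOURS).sum())
    if low_wear > MAX_LOW_WEAR_DAYS:
        return False, f"{low_wear} days with wear time < {MIN_WEAR_HOURS:.0f} h"
    if not (nights["day_type"] == "non-working").any():
        return False, "no non-working (weekend) day recorded"
    return True, ""


def nightly_midsleep(onset_axis_h: float, offset_axis_h: float) -> float:
    """Midsleep point = sleep onset + sleep duration / 2, as local clock time."""
    duration = offset_axis_h - onset_axis_h
    return mod24(onset_axis_h + duration / 2.0)


def weighted_week_mean(
    working_value: float,
    nonworking_value: float,
    weights: tuple[float, float] = (5.0 / 7.0, 2.0 / 7.0),
) -> float:
    """Weekly value as the weighted mean of the two day-type stratum means.

    Clock-time inputs must already be on a linear (noon-anchored or
    within-day) axis.  Default weights are 5/7 working, 2/7 non-working.
    """
    if working_value is None or nonworking_value is None or (
        np.isnan(working_value) or np.isnan(nonworking_value)
    ):
        raise ChronomealError("weighted week mean requires both day-type strata")
    w_work, w_non = weights
    return float(w_work * working_value + w_non * nonworking_value)


def social_jetlag(midsleep_working_axis: float, midsleep_nonworking_axis: float) -> float:
    """Signed social jetlag: non-working minus working midsleep (hours)."""
    if np.isnan(midsleep_working_axis) or np.isnan(midsleep_nonworking_axis):
        raise ChronomealError("social jetlag requires both day-type strata")
    return float(midsleep_nonworking_axis - midsleep_working_axis)


def summarize_participant_week(
    nights: pd.DataFrame,
    weights: tuple[float, float] = (5.0 / 7.0, 2.0 / 7.0),
) -> WeeklySleepSummary:
    """Weekly sleep summary for one participant (validity + weighted means)."""
    pid = str(nights["participant_id"].iloc[0]) if len(nights) else "?"
    valid, reason = is_valid_actigraphy(nights)
    if not valid:
        return WeeklySleepSummary(pid, np.nan, np.nan, np.nan, np.nan, np.nan, False, reason)
    msp_axis = nights["onset_axis_h"] + (nights["offset_axis_h"] - nights["onset_axis_h"]) / 2.0
    duration = nights["offset_axis_h"] - nights["onset_axis_h"]
    working = nights["day_type"] == "working"
    msp_w = float(msp_axis[working].mean())
    msp_nw = float(msp_axis[~working].mean())
    dur_w = float(duration[working].mean())
    dur_nw = float(duration[~working].mean())
    return WeeklySleepSummary(
        participant_id=pid,
        midsleep_week=mod24(weighted_week_mean(msp_w, msp_nw, weights)),
        midsleep_working=mod24(msp_w),
        midsleep_nonworking=mod24(msp_nw),
        sleep_duration_week=weighted_week_mean(dur_w, dur_nw, weights),
        social_jetlag=social_jetlag(msp_w, msp_nw),
        valid=True,
    )


def weekly_sleep_table(
    nights: pd.DataFrame,
    weights: tuple[float, float] = (5.0 / 7.0, 2.0 / 7.0),
) -> pd.DataFrame:
    """Vectorized weekly sleep summary across all participants.

    Midsleep columns are reported as clock hours; an additional
    ``midsleep_week_axis`` column keeps the noon-anchored value for
    downstream arithmetic.  Invalid participants keep their validity
    reason and NaN variables.
    """
    df = nights.copy()
    df["msp_axis"] = df["onset_axis_h"] + (df["offset_axis_h"] - df["onset_axis_h"]) / 2.0
    df["duration"] = df["offset_axis_h"] - df["onset_axis_h"]
    df["low_wear"] = df["wear_hours"] < MIN_WEAR_HOURS
    df["is_nonworking"] = df["day_type"] == "non-working"

    per = df.groupby("participant_id", sort=True, observed=True).agg(
        n_nights=("date", "size"),
        low_wear_days=("low_wear", "sum"),
        has_nonworking=("is_nonworking", "any"),
    )
    strata = (
        df.groupby(["participant_id", "day_type"], sort=True, observed=True)
        .agg(msp=("msp_axis", "mean"), dur=("duration", "mean"))
        .unstack("day_type")
    )
    for stat in ("msp", "dur"):
        for dt in ("working", "non-working"):
            if (stat, dt) not in strata.columns:
                strata[(stat, dt)] = np.nan
    per["msp_w"] = strata[("msp", "working")]
    per["msp_nw"] = strata[("msp", "non-working")]
    per["dur_w"] = strata[("dur", "working")]
    per["dur_nw"] = strata[("dur", "non-working")]

    valid = (
        (per["low_wear_days"] <= MAX_LOW_WEAR_DAYS)
        & per["has_nonworking"]
        & per["msp_w"].notna()
        & per["msp_nw"].notna()
    )
    reason = np.select(
        [
            per["low_wear_days"] > MAX_LOW_WEAR_DAYS,
            ~per["has_nonworking"],
            per["msp_w"].isna(),
        ],
        [
            per["low_wear_days"].astype(int).astype(str)
            + f" days with wear time < {MIN_WEAR_HOURS:.0f} h",
            "no non-working (weekend) day recorded",
            "no working day recorded",
        ],
        default="",
    )

    w_work, w_non = weights
    msp_axis = w_work * per["msp_w"] + w_non * per["msp_nw"]
    out = pd.DataFrame(
        {
            "participant_id": per.index.astype(str),
            "midsleep_week": mod24(msp_axis.to_numpy()),
            "midsleep_week_axis": msp_axis.to_numpy(),
            "midsleep_working": mod24(per["msp_w"].to_numpy()),
            "midsleep_nonworking": mod24(per["msp_nw"].to_numpy()),
            "sleep_duration_week": (w_work * per["dur_w"] + w_non * per["dur_nw"]).to_numpy(),
            "social_jetlag": (per["msp_nw"] - per["msp_w"]).to_numpy(),
            "social_jetlag_abs": (per["msp_nw"] - per["msp_w"]).abs().to_numpy(),
            "valid_actigraphy": valid.to_numpy(),
            "invalid_reason": reason,
        }
    ).reset_index(drop=True)
    value_cols = [
        "midsleep_week",
        "midsleep_week_axis",
        "midsleep_working",
        "midsleep_nonworking",
        "sleep_duration_week",
        "social_jetlag",
        "social_jetlag_abs",
    ]
    out.loc[~out["valid_actigraphy"], value_cols] = np.nan
    return out
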