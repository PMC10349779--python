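"""Meal-timing exposures referenced to the sleep/wake cycle.

Five headline weekly exposures are computed per participant:

* **eating window** — time between the first and last caloric intake of
  a day, weekly 5/7-2/7 weighted mean;
* **caloric midpoint** — the local time at which the running cumulative
  energy first reaches >= 50% of the day's total;
* **eating jetlag** — non-working minus working eating midpoint, where
  the eating midpoint is the temporal midpoint of the eating window
  (this is the construct of the chronobiology literature on eating
  jetlag; the caloric midpoint is reported alongside it);
* **time from the midsleep point to first intake** and **from last
  intake to the midsleep point** — computed from weekly means of each
  quantity (recall days and actigraphy nights do not overlap by design,
  so day-matched pairing is impossible), reduced mod 24 into (0, 24).

All arithmetic happens on the within-day axis (late-night events of a
recall day map to hour+24), so the identity
``msp_to_first + eating_window + last_to_msp = 24`` holds exactly for a
single day referenced to a single midsleep point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ChronomealError, ClassificationError
from .recall_io import RecallDay
from .timeaxis import mod24

WEEK_WEIGHTS = (5.0 / 7.0, 2.0 / 7.0)


# --------------------------------------------------------------------------
# per-day operations
# --------------------------------------------------------------------------

def daily_eating_window(day: RecallDay) -> float:
    """Hours between first and last caloric intake of one recall day."""
    ev = day.caloric_events
    if len(ev) == 0:
        return np.nan
    t = ev["axis_time"]
    return float(t.max() - t.min())


def daily_eating_midpoint(day: RecallDay) -> float:
    """Temporal midpoint of the eating window, on the within-day axis."""
    ev = day.caloric_events
    if len(ev) == 0:
        return np.nan
    t = ev["axis_time"]
    return float((t.min() + t.max()) / 2.0)


def daily_caloric_midpoint(day: RecallDay) -> float:
    """Within-day axis time at which cumulative energy first reaches >= 50%.

    Each event's energy is counted at its clock time; the earliest event
    whose running total reaches half the daily total defines the
    midpoint.
    """
    ev = day.caloric_events.sort_values("axis_time", kind="mergesort")
    total = ev["energy_kcal"].sum()
    if total <= 0:
        return np.nan
    cum = ev["energy_kcal"].cumsum()
    reached = ev.loc[cum >= 0.5 * total, "axis_time"]
    return float(reached.iloc[0])


def eating_jetlag(midpoint_working_axis: float, midpoint_nonworking_axis: float) -> float:
    """Signed eating jetlag (h): non-working minus working eating midpoint."""
    if np.isnan(midpoint_working_axis) or np.isnan(midpoint_nonworking_axis):
        return np.nan
    return float(midpoint_nonworking_axis - midpoint_working_axis)


def msp_to_first_intake(weekly_first_intake: float, midsleep_week: float) -> float:
    """(weekly first intake - weekly midsleep) mod 24, in (0, 24).

    A value near 24 flags an implausible ordering (first intake before
    midsleep) for QC.
    """
    if np.isnan(weekly_first_intake) or np.isnan(midsleep_week):
        return np.nan
    return float(np.mod(weekly_first_intake - midsleep_week, 24.0))


def last_intake_to_msp(weekly_last_intake: float, midsleep_week: float) -> float:
    """(weekly midsleep - weekly last intake) mod 24, in (0, 24)."""
    if np.isnan(weekly_last_intake) or np.isnan(midsleep_week):
        return np.nan
    return float(np.mod(midsleep_week - weekly_last_intake, 24.0))


def classify_breakfast(
    days: list[RecallDay],
    cutoff_h: float = 11.0,
    min_kcal: float = 50.0,
) -> str:
    """Breakfast status from exactly three recall days.

    A participant is a ``consumer`` iff every recall day has a caloric
    event of at least ``min_kcal`` no later than ``cutoff_h`` on the
    within-day axis (a post-midnight snack never qualifies); an event
    labeled "breakfast" overrides the time rule.  Anything else is a
    ``skipper``.
    """
    if len(days) != 3:
        raise ClassificationError(
            f"breakfast classification requires exactly 3 recall days, got {len(days)}"
        )
    for day in days:
        ev = day.caloric_events
        labeled = ev["meal_label"].astype(str).str.lower().eq("breakfast").any()
        timed = (
            (ev["energy_kcal"] >= min_kcal) & (ev["axis_time"] <= cutoff_h)
        ).any()
        if not (labeled or timed):
            return "skipper"
    return "consumer"


# --------------------------------------------------------------------------
# vectorized day-level and weekly tables
# --------------------------------------------------------------------------

def daily_metrics_table(events: pd.DataFrame) -> pd.DataFrame:
    """Day-level metrics for every (participant, date) in an event table.

    Expects a clean (reconciled, single-entry) event table with
    ``axis_time``, ``energy_kcal`` and ``is_caloric`` columns.
    """
    cal = events[events["is_caloric"]].sort_values(
        ["participant_id", "date", "axis_time"], kind="mergesort"
    )
    g = cal.groupby(["participant_id", "date"], sort=True, observed=True)
    out = g.agg(
        day_type=("day_type", "first"),
        first_axis=("axis_time", "min"),
        last_axis=("axis_time", "max"),
        total_energy=("energy_kcal", "sum"),
        n_events=("axis_time", "size"),
    )
    out["eating_window"] = out["last_axis"] - out["first_axis"]
    out["eating_midpoint_axis"] = (out["first_axis"] + out["last_axis"]) / 2.0
    cum = g["energy_kcal"].cumsum()
    total = g["energy_kcal"].transform("sum")
    reached = cal.loc[(cum >= 0.5 * total).to_numpy()]
    out["caloric_midpoint_axis"] = reached.groupby(
        ["participant_id", "date"], sort=True, observed=True
    )["axis_time"].first()
    return out.reset_index()


def weekly_chrono_table(
    daily: pd.DataFrame,
    sleep_weekly: pd.DataFrame,
    weights: tuple[float, float] = WEEK_WEIGHTS,
) -> pd.DataFrame:
    """Weekly meal-timing exposures per participant.

    ``daily`` is the output of :func:`daily_metrics_table`;
    ``sleep_weekly`` the output of
    :func:`chronomeal.sleep_metrics.weekly_sleep_table` (supplies
    ``midsleep_week_axis``).  Participants missing a day-type stratum
    get NaN weekly values (they are excluded upstream).
    """
    w_work, w_non = weights
    strata = (
        daily.groupby(["participant_id", "day_type"], sort=True, observed=True)
        .agg(
            window=("eating_window", "mean"),
            first=("first_axis", "mean"),
            last=("last_axis", "mean"),
            emid=("eating_midpoint_axis", "mean"),
            cmid=("caloric_midpoint_axis", "mean"),
        )
        .unstack("day_type")
    )
    for stat in ("window", "first", "last", "emid", "cmid"):
        for dt in ("working", "non-working"):
            if (stat, dt) not in strata.columns:
                strata[(stat, dt)] = np.nan

    def week(stat):
        return w_work * strata[(stat, "working")] + w_non * strata[(stat, "non-working")]

    out = pd.DataFrame(index=strata.index)
    out["eating_window"] = week("window")
    out["weekly_first_axis"] = week("first")
    out["weekly_last_axis"] = week("last")
    out["caloric_midpoint_axis"] = week("cmid")
    out["caloric_midpoint"] = mod24(out["caloric_midpoint_axis"].to_numpy())
    out["eating_midpoint_working"] = mod24(strata[("emid", "working")].to_numpy())
    out["eating_midpoint_nonworking"] = mod24(strata[("emid", "non-working")].to_numpy())
    out["eating_jetlag"] = strata[("emid", "non-working")] - strata[("emid", "working")]
    out["eating_jetlag_abs"] = out["eating_jetlag"].abs()
    out = out.reset_index()

    merged = out.merge(
        sleep_weekly[["participant_id", "midsleep_week_axis", "midsleep_week"]],
        on="participant_id",
        how="left",
    )
    merged["msp_to_first"] = np.mod(
        merged["weekly_first_axis"] - merged["midsleep_week_axis"], 24.0
    )
    merged["last_to_msp"] = np.mod(
        merged["midsleep_week_axis"] - merged["weekly_last_axis"], 24.0
    )
    return merged


def breakfast_status_table(
    events: pd.DataFrame,
    cutoff_h: float = 11.0,
    min_kcal: float = 50.0,
    expected_days: int = 3,
) -> pd.DataFrame:
    """Vectorized breakfast classification across participants.

    Participants with a number of recall days other than ``expected_days``
    get status "unclassifiable" rather than an exception (the per-
    participant operation :func:`classify_breakfast` raises instead).
    """
    cal = events[events["is_caloric"]]
    qualifies = (
        (cal["energy_kcal"] >= min_kcal) & (cal["axis_time"] <= cutoff_h)
    ) | cal["meal_label"].astype(str).str.lower().eq("breakfast")
    day_has = (
        cal.assign(q=qualifies)
        .groupby(["participant_id", "date"], sort=True, observed=True)["q"]
        .any()
    )
    per = day_has.groupby("participant_id").agg(n_days="size", all_days="all")
    status = np.where(
        per["n_days"] != expected_days,
        "unclassifiable",
        np.where(per["all_days"], "consumer", "skipper"),
    )
    return pd.DataFrame(
        {"participant_id": per.index.astype(str), "breakfast_status": status}
    ).reset_index(drop=True)


def check_closure(msp_to_first: float, eating_window: float, last_to_msp: float) -> float:
    """Sum of the two midsleep-anchored intervals and the eating window.

    Equals 24 exactly when all three derive from one day's first/last
    intake and a single midsleep point.
    """
    if any(np.isnan(v) for v in (msp_to_first, eating_window, last_to_msp)):
        raise ChronomealError("closure check requires all three intervals")
    return float(msp_to_first + eating_window + last_to_msp)
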