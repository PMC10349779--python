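"""Reading of 24-h dietary recall event tables and the dual-entry
coefficient-of-variation reconciliation rule.

Recalls are entered independently by two coders; when the coefficient of
variation (CV) of the two daily energy totals exceeds 5%, a third entry
is required and the pair with the best agreement (lowest CV) is averaged
event-wise.  The CV is computed on the daily total energy with the
sample (n-1) SD convention — the standard dietetics choice; which
quantity the original protocol targeted is not documented, so this is
the package's contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ReconciliationError, RowParseError, SchemaError, UndefinedCVError
from .timeaxis import DEFAULT_ROLLOVER_HOUR, parse_clock, to_day_axis

REQUIRED_COLUMNS = ("participant_id", "date", "day_type", "time", "energy_kcal")
OPTIONAL_COLUMNS = ("meal_label", "entry_id")
DAY_TYPES = frozenset({"working", "non-working"})


@dataclass(eq=False)
class RecallDay:
    """One participant-day of caloric eating events, time-ordered on the
    within-day axis."""

    participant_id: str
    date: Date
    day_type: str
    events: pd.DataFrame  # columns incl. axis_time, energy_kcal, is_caloric

    @property
    def total_energy(self) -> float:
        return float(self.events["energy_kcal"].sum())

    @property
    def caloric_events(self) -> pd.DataFrame:
        return self.events[self.events["is_caloric"]]


def read_recall_table(
    path: str | Path,
    rollover_hour: float = DEFAULT_ROLLOVER_HOUR,
    caloric_threshold_kcal: float = 0.0,
) -> pd.DataFrame:
    """Read a recall-event CSV into a typed event table.

    Rows with energy at or below ``caloric_threshold_kcal`` are retained
    but flagged non-caloric.  Raises :class:`SchemaError` for a missing
    required column and :class:`RowParseError` (with the 1-based file
    line number) for an unparseable time, date or energy.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = ""

    clock = np.empty(len(df))
    dates = []
    energy = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            clock[i] = parse_clock(row.time)
        except ValueError as exc:
            raise RowParseError(str(exc), line=line) from None
        try:
            dates.append(pd.Timestamp(row.date).date())
        except ValueError:
            raise RowParseError(f"unparseable date: {row.date!r}", line=line) from None
        try:
            energy[i] = float(row.energy_kcal)
        except ValueError:
            raise RowParseError(f"unparseable energy: {row.energy_kcal!r}", line=line) from None
        if energy[i] < 0:
            raise RowParseError(f"negative energy: {row.energy_kcal!r}", line=line)
        if row.day_type not in DAY_TYPES:
            raise RowParseError(
                f"day_type must be one of {sorted(DAY_TYPES)}, got {row.day_type!r}", line=line
            )

    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].astype(str),
            "date": dates,
            "day_type": df["day_type"].astype(str),
            "clock_time": clock,
            "axis_time": to_day_axis(clock, rollover_hour),
            "energy_kcal": energy,
            "meal_label": df["meal_label"].astype(str),
            "entry_id": df["entry_id"].astype(str),
        }
    )
    out["is_caloric"] = out["energy_kcal"] > caloric_threshold_kcal
    return out.sort_values(
        ["participant_id", "date", "entry_id", "axis_time"], kind="mergesort"
    ).reset_index(drop=True)


def split_recall_days(events: pd.DataFrame) -> list[RecallDay]:
    """Split an event table into per-(participant, date, entry) RecallDays."""
    days = []
    keys = ["participant_id", "date", "entry_id"] if "entry_id" in events else [
        "participant_id", "date"
    ]
    for key, grp in events.groupby(keys, sort=True, observed=True):
        grp = grp.sort_values("axis_time", kind="mergesort").reset_index(drop=True)
        days.append(
            RecallDay(
                participant_id=str(key[0]),
                date=key[1],
                day_type=str(grp["day_type"].iloc[0]),
                events=grp,
            )
        )
    return days


def energy_cv(total_a: float, total_b: float) -> float:
    """Percent coefficient of variation of two daily energy totals
    (sample SD, n-1 denominator).

    ``energy_cv(100, 110)`` is 6.734%.  Undefined when both totals are
    zero.
    """
    mean = (total_a + total_b) / 2.0
    if mean == 0:
        raise UndefinedCVError("CV undefined: both daily totals are zero")
    sd = abs(total_a - total_b) / np.sqrt(2.0)  # n-1 SD of two values
    return float(100.0 * sd / mean)


def _eventwise_mean(a: RecallDay, b: RecallDay) -> RecallDay:
    if len(a.events) != len(b.events):
        raise ReconciliationError(
            f"{a.participant_id} {a.date}: entries have {len(a.events)} vs "
            f"{len(b.events)} events; event-wise averaging is ambiguous"
        )
    ev = a.events.copy()
    ev["axis_time"] = (a.events["axis_time"].to_numpy() + b.events["axis_time"].to_numpy()) / 2.0
    ev["clock_time"] = ev["axis_time"] % 24.0
    ev["energy_kcal"] = (
        a.events["energy_kcal"].to_numpy() + b.events["energy_kcal"].to_numpy()
    ) / 2.0
    ev["entry_id"] = ""
    ev["is_caloric"] = ev["energy_kcal"] > 0
    return RecallDay(a.participant_id, a.date, a.day_type, ev.reset_index(drop=True))


def reconcile_dual_entry(
    entry_a: RecallDay,
    entry_b: RecallDay,
    entry_c: RecallDay | None = None,
    cv_threshold_pct: float = 5.0,
) -> RecallDay:
    """Apply the dual-entry reconciliation rule to one participant-day.

    If CV(a, b) <= threshold the event-wise mean of a and b is returned.
    Otherwise a third entry is required and the pair with the lowest CV
    is averaged; exact CV ties prefer a pair containing the third entry.
    """
    for other in filter(None, (entry_b, entry_c)):
        if (other.participant_id, other.date) != (entry_a.participant_id, entry_a.date):
            raise ReconciliationError(
                f"entries refer to different participant-days: "
                f"{(entry_a.participant_id, entry_a.date)} vs "
                f"{(other.participant_id, other.date)}"
            )
    cv_ab = energy_cv(entry_a.total_energy, entry_b.total_energy)
    if cv_ab <= cv_threshold_pct:
        return _eventwise_mean(entry_a, entry_b)
    if entry_c is None:
        raise ReconciliationError(
            f"{entry_a.participant_id} {entry_a.date}: CV {cv_ab:.2f}% > "
            f"{cv_threshold_pct}% but no third entry supplied"
        )
    candidates = list(combinations([entry_a, entry_b, entry_c], 2))
    cvs = [energy_cv(x.total_energy, y.total_energy) for x, y in candidates]
    best_cv = min(cvs)
    best = [
        pair
        for pair, cv in zip(candidates, cvs)
        if cv == best_cv
    ]
    # tie-break: prefer the freshly re-entered dataset
    best.sort(key=lambda pair: any(p is entry_c for p in pair), reverse=True)
    return _eventwise_mean(*best[0])


def reconcile_events_table(
    events: pd.DataFrame, cv_threshold_pct: float = 5.0
) -> tuple[pd.DataFrame, list[dict]]:
    """Vectorized dual-entry reconciliation of a full event table.

    Semantically identical to applying :func:`reconcile_dual_entry` per
    participant-day (entry roles are the lexicographically sorted entry
    IDs of a day); returns one clean single-entry event table plus a log
    of participant-days that failed reconciliation.  Days that carry a
    single entry pass through unchanged.
    """
    ev = events.sort_values(
        ["participant_id", "date", "entry_id", "axis_time"], kind="mergesort"
    ).reset_index(drop=True)
    entry_keys = ev[["participant_id", "date", "entry_id"]].drop_duplicates()
    entry_keys["entry_pos"] = entry_keys.groupby(
        ["participant_id", "date"], sort=True, observed=True
    ).cumcount()
    ev = ev.merge(entry_keys, on=["participant_id", "date", "entry_id"], how="left")

    day_grp = ev.groupby(["participant_id", "date", "entry_pos"], sort=True, observed=True)
    totals = day_grp["energy_kcal"].sum().unstack("entry_pos")
    counts = day_grp["energy_kcal"].size().unstack("entry_pos")
    for pos in (0, 1, 2):
        if pos not in totals.columns:
            totals[pos] = np.nan
            counts[pos] = np.nan

    single = totals[1].isna()
    a, b, c = (totals[i].to_numpy() for i in (0, 1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        def _cv(x, y):
            return 100.0 * np.abs(x - y) / np.sqrt(2.0) / ((x + y) / 2.0)

        cv_ab, cv_ac, cv_bc = _cv(a, b), _cv(a, c), _cv(b, c)
    need_third = cv_ab > cv_threshold_pct
    has_c = ~np.isnan(c)

    # chosen entry positions per multi-entry day; ties prefer the pair
    # containing the re-entered third dataset
    choice1 = np.where(need_third, np.where(cv_ac <= cv_bc, 0, 1), 0)
    choice2 = np.where(need_third, 2, 1)
    use_ab = need_third & has_c & (cv_ab < np.fmin(cv_ac, cv_bc))
    choice1 = np.where(use_ab, 0, choice1)
    choice2 = np.where(use_ab, 1, choice2)

    cnt = counts.to_numpy()
    idx = np.arange(len(totals))
    count_mismatch = cnt[idx, choice1] != cnt[idx, choice2]
    undefined_cv = (a + b) == 0
    failed = (~single.to_numpy()) & (
        (need_third & ~has_c) | count_mismatch | undefined_cv
    )
    failures = [
        {
            "participant_id": pid,
            "date": date,
            "reason": "CV > threshold with no third entry"
            if nt and not hc
            else ("undefined CV (zero totals)" if uc else "entry event counts differ"),
        }
        for (pid, date), nt, hc, uc in zip(
            totals.index[failed],
            need_third[failed],
            has_c[failed],
            undefined_cv[failed],
        )
    ]

    reconcile = (~single.to_numpy()) & ~failed
    day_info = pd.DataFrame(
        {
            "choice1": choice1,
            "choice2": choice2,
            "single": single.to_numpy(),
            "failed": failed,
        },
        index=totals.index,
    ).reset_index()

    ev = ev.merge(day_info, on=["participant_id", "date"], how="left")
    passthrough = ev[ev["single"]].drop(
        columns=["entry_pos", "choice1", "choice2", "single", "failed"]
    )

    multi = ev[~ev["single"] & ~ev["failed"]].copy()
    multi["rank"] = multi.groupby(
        ["participant_id", "date", "entry_pos"], sort=False, observed=True
    ).cumcount()
    sel1 = multi[multi["entry_pos"] == multi["choice1"]]
    sel2 = multi[multi["entry_pos"] == multi["choice2"]]
    merged = sel1.merge(
        sel2[["participant_id", "date", "rank", "axis_time", "energy_kcal"]],
        on=["participant_id", "date", "rank"],
        suffixes=("", "_2"),
    )
    merged["axis_time"] = (merged["axis_time"] + merged["axis_time_2"]) / 2.0
    merged["energy_kcal"] = (merged["energy_kcal"] + merged["energy_kcal_2"]) / 2.0
    merged["clock_time"] = merged["axis_time"] % 24.0
    merged["entry_id"] = ""
    merged["is_caloric"] = merged["energy_kcal"] > 0
    merged = merged.drop(
        columns=[
            "axis_time_2",
            "energy_kcal_2",
            "rank",
            "entry_pos",
            "choice1",
            "choice2",
            "single",
            "failed",
        ]
    )
    clean = pd.concat([passthrough, merged], ignore_index=True)
    assert reconcile.sum() + single.sum() + failed.sum() == len(totals)
    return (
        clean.sort_values(
            ["participant_id", "date", "axis_time"], kind="mergesort"
        ).reset_index(drop=True),
        failures,
    )


def reconcile_table(
    events: pd.DataFrame, cv_threshold_pct: float = 5.0
) -> tuple[list[RecallDay], list[dict]]:
    """Reconcile a full (possibly dual-entry) event table.

    Returns clean RecallDays (one per participant-day) and a log of
    participant-days that failed reconciliation.
    """
    clean: list[RecallDay] = []
    failures: list[dict] = []
    for (pid, date), grp in events.groupby(["participant_id", "date"], sort=True, observed=True):
        entries = split_recall_days(grp)
        if len(entries) == 1:
            day = entries[0]
            clean.append(
                RecallDay(day.participant_id, day.date, day.day_type, day.events.reset_index(drop=True))
            )
            continue
        by_id = {d.events["entry_id"].iloc[0]: d for d in entries}
        try:
            a = by_id.get("A") or entries[0]
            b = by_id.get("B") or entries[1]
            c = by_id.get("C")
            clean.append(reconcile_dual_entry(a, b, c, cv_threshold_pct))
        except (ReconciliationError, UndefinedCVError) as exc:
            failures.append({"participant_id": pid, "date": date, "reason": str(exc)})
    return clean, failures
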