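"""Meal-timing exposures: windows, midpoints, midsleep-anchored intervals,
breakfast status."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronomeal.chrono_metrics import (
    check_closure,
    classify_breakfast,
    daily_caloric_midpoint,
    daily_eating_midpoint,
    daily_eating_window,
    daily_metrics_table,
    eating_jetlag,
    last_intake_to_msp,
    msp_to_first_intake,
)
from chronomeal.errors import ClassificationError

from conftest import make_recall_day


class TestDailyWindowAndMidpoints:
    def test_window_first_to_last(self):
        day = make_recall_day([8.0, 12.0, 20.5], [300, 600, 500])
        assert daily_eating_window(day) == pytest.approx(12.5)

    def test_single_event_window_zero(self):
        day = make_recall_day([9.0], [300])
        assert daily_eating_window(day) == pytest.approx(0.0)
        assert daily_eating_midpoint(day) == pytest.approx(9.0)
        assert daily_caloric_midpoint(day) == pytest.approx(9.0)

    def test_post_midnight_last_event(self):
        # first 10:00, last 00:30 of the next calendar day -> 14.5 h window
        day = make_recall_day([10.0, 24.5], [500, 300])
        assert daily_eating_window(day) == pytest.approx(14.5)
        assert daily_eating_midpoint(day) == pytest.approx(17.25)

    def test_non_caloric_events_ignored(self):
        day = make_recall_day([6.0, 8.0, 20.0], [0.0, 300, 500])
        assert daily_eating_window(day) == pytest.approx(12.0)

    def test_no_caloric_events_missing(self):
        day = make_recall_day([8.0], [0.0])
        assert np.isnan(daily_eating_window(day))

    @pytest.mark.parametrize(
        "times,energies,expected",
        [
            ([8.0, 13.0, 20.0], [300, 300, 300], 13.0),  # 600/900 >= 50% at 13:00
            ([8.0, 13.0, 20.0], [500, 100, 100], 8.0),  # 500/700 >= 50% at first
            ([8.0, 20.0], [100, 900], 20.0),
        ],
    )
    def test_caloric_midpoint_cumulative_rule(self, times, energies, expected):
        day = make_recall_day(times, energies)
        assert daily_caloric_midpoint(day) == pytest.approx(expected)

    @given(
        times=st.lists(st.floats(5.0, 27.0), min_size=1, max_size=8),
        seed=st.integers(0, 1000),
    )
    @settings(derandomize=True, max_examples=150)
    def test_caloric_midpoint_inside_eating_window(self, times, seed):
        rng = np.random.default_rng(seed)
        energies = rng.uniform(50, 800, size=len(times))
        day = make_recall_day(sorted(times), energies)
        mid = daily_caloric_midpoint(day)
        assert min(times) - 1e-9 <= mid <= max(times) + 1e-9


class TestEatingJetlag:
    @pytest.mark.parametrize(
        "w,nw,expected", [(13.8, 15.0, 1.2), (14.0, 14.0, 0.0), (14.5, 13.0, -1.5)]
    )
    def test_signed_nonworking_minus_working(self, w, nw, expected):
        assert eating_jetlag(w, nw) == pytest.approx(expected)

    def test_missing_stratum_is_missing(self):
        assert np.isnan(eating_jetlag(np.nan, 15.0))


class TestMidsleepAnchoredIntervals:
    def test_table_consistent_morning_interval(self):
        # midsleep 05:04, first intake 09:56 -> 4.87 h
        assert msp_to_first_intake(9.0 + 56 / 60, 5.0 + 4 / 60) == pytest.approx(4.8667, abs=1e-3)

    def test_evening_interval(self):
        # last intake 22:01, midsleep 05:04 (next day) -> 7.05 h
        assert last_intake_to_msp(22.0 + 1 / 60, 5.0 + 4 / 60) == pytest.approx(7.05, abs=1e-3)

    def test_additive_offset(self):
        assert msp_to_first_intake(4.0 + 3.2, 4.0) == pytest.approx(3.2)
        assert last_intake_to_msp(5.0 - 8.0 + 24.0, 5.0) == pytest.approx(8.0)

    def test_implausible_ordering_flags_near_24(self):
        assert msp_to_first_intake(4.0, 5.0) == pytest.approx(23.0)
        assert last_intake_to_msp(6.0, 5.0) == pytest.approx(23.0)

    @given(
        midsleep=st.floats(1.0, 9.0),
        gap=st.floats(0.5, 8.0),
        window=st.floats(2.0, 15.5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_per_day_closure_identity(self, midsleep, gap, window):
        """msp_to_first + window + last_to_msp == 24 for one day and one
        midsleep point (both intakes within 24 h of the midsleep)."""
        first = midsleep + gap
        last = first + window
        total = check_closure(
            msp_to_first_intake(first, midsleep),
            window,
            last_intake_to_msp(last, midsleep),
        )
        assert total == pytest.approx(24.0, abs=1e-9)


class TestBreakfastClassification:
    def _days(self, first_times, energies=300.0):
        return [
            make_recall_day([t, 14.0, 21.0], [energies, 600, 500], date=f"2016-10-{10 + i}")
            for i, t in enumerate(first_times)
        ]

    def test_morning_eaters_are_consumers(self):
        assert classify_breakfast(self._days([8.5, 8.5, 8.5])) == "consumer"

    def test_one_late_day_makes_skipper(self):
        assert classify_breakfast(self._days([8.5, 8.5, 13.0])) == "skipper"

    def test_subthreshold_morning_energy_skips(self):
        assert classify_breakfast(self._days([7.0, 7.0, 7.0], energies=20.0), min_kcal=50) == "skipper"

    def test_breakfast_label_overrides_time_rule(self):
        days = [
            make_recall_day(
                [13.0, 21.0], [400, 500], labels=["breakfast", ""], date=f"2016-10-{10 + i}"
            )
            for i in range(3)
        ]
        assert classify_breakfast(days) == "consumer"

    def test_requires_exactly_three_days(self):
        with pytest.raises(ClassificationError):
            classify_breakfast(self._days([8.5, 8.5]))


def test_daily_metrics_table_matches_per_day_operations(small_cohort):
    """Vectorized day-level table must agree with the scalar operations."""
    from chronomeal.recall_io import split_recall_days

    events = small_cohort.recall_events
    sample_pids = events["participant_id"].unique()[:8]
    sub = events[events["participant_id"].isin(sample_pids)]
    table = daily_metrics_table(sub).set_index(["participant_id", "date"])
    for day in split_recall_days(sub.drop(columns="entry_id")):
        row = table.loc[(day.participant_id, day.date)]
        assert row["eating_window"] == pytest.approx(daily_eating_window(day))
        assert row["eating_midpoint_axis"] == pytest.approx(daily_eating_midpoint(day))
        assert row["caloric_midpoint_axis"] == pytest.approx(daily_caloric_midpoint(day))
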