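"""Recall-table IO and the dual-entry CV reconciliation rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronomeal.errors import (
    ReconciliationError,
    RowParseError,
    SchemaError,
    UndefinedCVError,
)
from chronomeal.recall_io import (
    energy_cv,
    read_recall_table,
    reconcile_dual_entry,
    reconcile_events_table,
    split_recall_days,
)

from conftest import make_recall_day


def _write_csv(tmp_path, text, name="recalls.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = "participant_id,date,day_type,time,energy_kcal,meal_label,entry_id\n"


class TestReadRecallTable:
    def test_well_formed_rows_are_typed_events(self, tmp_path):
        path = _write_csv(
            tmp_path,
            HEADER
            + "P1,2016-10-10,working,08:30,300,breakfast,A\n"
            + "P1,2016-10-10,working,13:00,650,,A\n"
            + "P1,2016-10-10,working,00:30,150,,A\n",
        )
        events = read_recall_table(path)
        assert len(events) == 3
        # the 00:30 snack belongs to the same recall day -> axis 24.5, last
        assert events["axis_time"].tolist() == [8.5, 13.0, 24.5]
        assert events["is_caloric"].all()

    def test_missing_energy_column_is_schema_error(self, tmp_path):
        path = _write_csv(
            tmp_path,
            "participant_id,date,day_type,time\nP1,2016-10-10,working,08:30\n",
        )
        with pytest.raises(SchemaError, match="energy_kcal"):
            read_recall_table(path)

    def test_out_of_range_time_reports_line_number(self, tmp_path):
        path = _write_csv(
            tmp_path,
            HEADER + "P1,2016-10-10,working,08:30,300,,A\nP1,2016-10-10,working,25:30,200,,A\n",
        )
        with pytest.raises(RowParseError, match="line 3"):
            read_recall_table(path)

    def test_subthreshold_energy_flagged_non_caloric(self, tmp_path):
        path = _write_csv(
            tmp_path,
            HEADER + "P1,2016-10-10,working,08:30,3,,A\nP1,2016-10-10,working,13:00,650,,A\n",
        )
        events = read_recall_table(path, caloric_threshold_kcal=5.0)
        assert events["is_caloric"].tolist() == [False, True]
        assert len(events) == 2  # retained, not dropped


class TestEnergyCV:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (2000.0, 2000.0, 0.0),
            (100.0, 110.0, 6.7343),  # sd([100,110], n-1)/105*100
            (95.0, 105.0, 7.0711),
        ],
    )
    def test_sample_sd_convention(self, a, b, expected):
        assert energy_cv(a, b) == pytest.approx(expected, abs=1e-3)

    def test_undefined_for_zero_totals(self):
        with pytest.raises(UndefinedCVError):
            energy_cv(0.0, 0.0)

    @given(
        a=st.floats(1.0, 5000.0),
        b=st.floats(1.0, 5000.0),
        k=st.floats(0.01, 100.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_symmetric_and_scale_invariant(self, a, b, k):
        assert energy_cv(a, b) == pytest.approx(energy_cv(b, a), rel=1e-12)
        assert energy_cv(k * a, k * b) == pytest.approx(energy_cv(a, b), rel=1e-9)


class TestReconcileDualEntry:
    def test_identical_entries_returned_unchanged(self):
        a = make_recall_day([8.0, 13.0, 20.0], [300, 600, 500])
        b = make_recall_day([8.0, 13.0, 20.0], [300, 600, 500])
        out = reconcile_dual_entry(a, b)
        assert out.total_energy == a.total_energy
        assert out.events["axis_time"].tolist() == [8.0, 13.0, 20.0]

    def test_high_cv_picks_best_agreeing_pair_with_third(self):
        # totals 100 vs 110 -> CV 6.73% > 5%; third entry 101 pairs with A
        a = make_recall_day([9.0], [100.0])
        b = make_recall_day([9.0], [110.0])
        c = make_recall_day([9.0], [101.0])
        out = reconcile_dual_entry(a, b, c)
        assert out.total_energy == pytest.approx(100.5)

    def test_high_cv_without_third_entry_fails(self):
        a = make_recall_day([9.0], [100.0])
        b = make_recall_day([9.0], [110.0])
        with pytest.raises(ReconciliationError, match="no third entry"):
            reconcile_dual_entry(a, b)

    def test_mismatched_event_counts_fail_loudly(self):
        a = make_recall_day([9.0, 14.0], [100.0, 200.0])
        b = make_recall_day([9.0], [305.0])
        with pytest.raises(ReconciliationError, match="event"):
            reconcile_dual_entry(a, b)

    def test_reconciled_total_is_mean_of_chosen_pair(self):
        a = make_recall_day([8.0, 20.0], [500.0, 480.0])
        b = make_recall_day([8.1, 20.2], [510.0, 500.0])
        out = reconcile_dual_entry(a, b)
        assert out.total_energy == pytest.approx((980.0 + 1010.0) / 2)
        # times averaged event-wise on the within-day axis
        assert out.events["axis_time"].tolist() == pytest.approx([8.05, 20.1])


def test_vectorized_reconciliation_matches_per_day_rule():
    """The table-level fast path must agree with the scalar rule."""
    rows = []
    for pid, totals in [
        ("P1", {"A": [300, 700], "B": [310, 705]}),  # CV below threshold
        ("P2", {"A": [100], "B": [110], "C": [101]}),  # needs the third entry
    ]:
        for entry, energies in totals.items():
            for i, e in enumerate(energies):
                rows.append(
                    {
                        "participant_id": pid,
                        "date": pd.Timestamp("2016-10-10").date(),
                        "day_type": "working",
                        "clock_time": 9.0 + i * 5,
                        "axis_time": 9.0 + i * 5,
                        "energy_kcal": float(e),
                        "meal_label": "",
                        "entry_id": entry,
                        "is_caloric": True,
                    }
                )
    events = pd.DataFrame(rows)
    clean, failures = reconcile_events_table(events)
    assert not failures
    totals = clean.groupby("participant_id")["energy_kcal"].sum()
    assert totals["P1"] == pytest.approx((1000 + 1015) / 2)
    assert totals["P2"] == pytest.approx(100.5)


def test_split_recall_days_orders_events_on_day_axis():
    events = pd.DataFrame(
        {
            "participant_id": ["P1"] * 3,
            "date": [pd.Timestamp("2016-10-10").date()] * 3,
            "day_type": ["working"] * 3,
            "clock_time": [0.5, 10.0, 20.0],
            "axis_time": [24.5, 10.0, 20.0],
            "energy_kcal": [150.0, 400.0, 600.0],
            "meal_label": [""] * 3,
            "entry_id": ["A"] * 3,
            "is_caloric": [True] * 3,
        }
    )
    (day,) = split_recall_days(events)
    assert day.events["axis_time"].tolist() == [10.0, 20.0, 24.5]
    assert day.total_energy == pytest.approx(1150.0)
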