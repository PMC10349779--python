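import pandas as pd
import pytest

from chronomeal.config import CohortConfig, Conventions
from chronomeal.pipeline import derive_participant_table
from chronomeal.synthetic import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_participants=200, seed=11))


@pytest.fixture(scope="session")
def derived_small(small_cohort):
    derived, report = derive_participant_table(
        small_cohort.recall_events,
        small_cohort.sleep_nights,
        small_cohort.participants,
        Conventions(),
    )
    return derived


def make_recall_day(times, energies, pid="P1", date="2016-10-10", day_type="working",
                    labels=None):
    """Build a RecallDay from within-day axis times and energies."""
    from chronomeal.recall_io import RecallDay

    n = len(times)
    ev = pd.DataFrame(
        {
            "participant_id": pid,
            "date": pd.Timestamp(date).date(),
            "day_type": day_type,
            "clock_time": [t % 24 for t in times],
            "axis_time": list(map(float, times)),
            "energy_kcal": list(map(float, energies)),
            "meal_label": labels if labels is not None else [""] * n,
            "entry_id": "A",
        }
    )
    ev["is_caloric"] = ev["energy_kcal"] > 0
    ev = ev.sort_values("axis_time", kind="mergesort").reset_index(drop=True)
    return RecallDay(pid, ev["date"].iloc[0], day_type, ev)
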