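import datetime as dt

import numpy as np
import pytest

from actirhythm.core import MINUTES_PER_DAY, CleanSeries, CutPoints, DayRecord, MinuteSeries
from actirhythm.preprocess import preprocess_series
from actirhythm.synthetic import GroupParams, default_group_params, simulate_subject


def make_day(counts, date=dt.date(2022, 5, 2), mark=True):
    """DayRecord from a 1440 count vector, optionally wear/valid-marked."""
    day = DayRecord(date=date, counts=np.asarray(counts, dtype=float))
    if mark:
        from actirhythm.preprocess import detect_nonwear, mark_valid_day

        day = mark_valid_day(detect_nonwear(day))
    return day


def make_clean(day_counts, subject_id="S1"):
    """CleanSeries from a list of 1440-vectors (all days assumed valid)."""
    days = [make_day(c, date=dt.date(2022, 5, 2) + dt.timedelta(days=i)) for i, c in enumerate(day_counts)]
    for d in days:
        if not d.valid:
            raise ValueError("fixture day not valid; choose nonzero counts")
    return CleanSeries(subject_id, days)


@pytest.fixture(scope="session")
def cutpoints():
    return CutPoints()


@pytest.fixture(scope="session")
def pms_params():
    return default_group_params()["PMS"]


@pytest.fixture(scope="session")
def clean_subject(pms_params):
    """One preprocessed simulated subject (7 days)."""
    series, _ = simulate_subject(pms_params, 7, seed=42)
    clean, _ = preprocess_series(series)
    assert isinstance(clean, CleanSeries)
    return clean
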