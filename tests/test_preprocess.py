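"""Nonwear, valid-day, DST-resolution and inclusion rules."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actirhythm.core import MINUTES_PER_DAY, CleanSeries, Exclusion, MinuteSeries
from actirhythm.preprocess import (
    detect_nonwear,
    detect_nonwear_series,
    include_subject,
    mark_valid_day,
    nonwear_mask,
    preprocess_series,
    read_counts_csv,
    resolve_dst,
)
from actirhythm.synthetic import inject_dst, simulate_subject, write_counts_csv

from conftest import make_day


class TestNonwear:
    def test_all_zero_day_fully_flagged(self):
        day = detect_nonwear(make_day(np.zeros(MINUTES_PER_DAY), mark=False))
        assert not day.wear.any()

    @pytest.mark.parametrize(
        "run_len,expected_flagged", [(89, 0), (90, 90), (200, 200)]
    )
    def test_zero_run_threshold(self, run_len, expected_flagged):
        counts = np.full(MINUTES_PER_DAY, 100.0)
        counts[300 : 300 + run_len] = 0.0
        day = detect_nonwear(make_day(counts, mark=False))
        assert int((~day.wear).sum()) == expected_flagged

    def test_run_spanning_midnight_detected(self):
        # 50 zero minutes at the end of day 1 + 50 at the start of day 2:
        # invisible per-day, one 100-minute run on the concatenated series
        c1 = np.full(MINUTES_PER_DAY, 100.0)
        c2 = np.full(MINUTES_PER_DAY, 100.0)
        c1[-50:] = 0.0
        c2[:50] = 0.0
        series = MinuteSeries(
            "S1",
            [make_day(c1, mark=False), make_day(c2, date=dt.date(2022, 5, 3), mark=False)],
        )
        flagged = detect_nonwear_series(series)
        assert not flagged.days[0].wear[-50:].any()
        assert not flagged.days[1].wear[:50].any()
        per_day = [detect_nonwear(d) for d in series.days]
        assert per_day[0].wear.all() and per_day[1].wear.all()

    @given(
        fill=st.integers(min_value=1, max_value=10000),
        start=st.integers(min_value=0, max_value=1340),
        run=st.integers(min_value=0, max_value=100),
    )
    @settings(max_examples=50, deadline=None)
    def test_flagging_depends_only_on_zero_pattern(self, fill, start, run):
        """Nonwear flags are invariant to the values of nonzero minutes."""
        a = np.full(MINUTES_PER_DAY, float(fill))
        b = np.full(MINUTES_PER_DAY, 5000.0)
        a[start : start + run] = 0.0
        b[start : start + run] = 0.0
        assert np.array_equal(nonwear_mask(a), nonwear_mask(b))

    def test_missing_minutes_break_runs_and_are_not_wear(self):
        counts = np.full(MINUTES_PER_DAY, 0.0)
        counts[100:200] = np.nan
        wear = nonwear_mask(counts)
        assert not wear[100:200].any()
        assert not wear[:100].any() and not wear[200:].any()  # runs >= 90 remain


class TestValidDay:
    @pytest.mark.parametrize("wear_minutes,valid", [(1296, True), (1295, False), (1440, True)])
    def test_wear_minute_boundary(self, wear_minutes, valid):
        counts = np.full(MINUTES_PER_DAY, 100.0)
        counts[: MINUTES_PER_DAY - wear_minutes] = 0.0  # one long nonwear run
        day = mark_valid_day(detect_nonwear(make_day(counts, mark=False)))
        assert day.wear_minutes == wear_minutes
        assert day.valid is valid


class TestResolveDst:
    def _series(self, n_days=4, value=100.0):
        days = [
            make_day(np.full(MINUTES_PER_DAY, value), date=dt.date(2022, 3, 10 + i))
            for i in range(n_days)
        ]
        return MinuteSeries("S1", days)

    def test_forward_hour_imputed_from_other_days(self):
        series = inject_dst(self._series(), day=2, direction="forward")
        series.days = [mark_valid_day(d) for d in series.days]
        resolved, flags = resolve_dst(series)
        assert not flags
        assert np.allclose(resolved.days[2].counts[120:180], 100.0)
        assert resolved.days[2].wear.all()

    def test_duplicated_hour_averaged(self):
        series = self._series()
        series.days[1].counts[60:120] = 80.0
        series = inject_dst(
            series, day=1, direction="back", duplicate_values=np.full(60, 120.0)
        )
        series.days = [mark_valid_day(d) for d in series.days]
        resolved, _ = resolve_dst(series)
        assert np.allclose(resolved.days[1].counts[60:120], 100.0)
        # final day's short hour refilled from the other days
        assert np.allclose(resolved.days[-1].counts[1380:], 100.0)

    def test_no_event_is_identity(self):
        series = self._series()
        series.days = [mark_valid_day(d) for d in series.days]
        resolved, flags = resolve_dst(series)
        assert not flags
        for before, after in zip(series.days, resolved.days):
            assert np.array_equal(before.counts, after.counts)
            assert np.array_equal(before.wear, after.wear)

    def test_no_valid_source_days_flags_subject(self):
        days = [make_day(np.full(MINUTES_PER_DAY, 100.0))]
        series = inject_dst(MinuteSeries("S1", days), day=0, direction="forward")
        series.days = [mark_valid_day(d) for d in series.days]
        resolved, flags = resolve_dst(series)
        assert flags
        assert np.isnan(resolved.days[0].counts[120:180]).all()

    def test_wear_minutes_conserved_without_dst(self):
        series, _ = simulate_subject(
            __import__("actirhythm").default_group_params()["PMS"], 4, seed=7
        )
        marked = detect_nonwear_series(series)
        marked.days = [mark_valid_day(d) for d in marked.days]
        before = [d.wear_minutes for d in marked.days]
        resolved, _ = resolve_dst(marked)
        assert [d.wear_minutes for d in resolved.days] == before


class TestInclusion:
    def _series_with_valid_days(self, n_valid, n_invalid=0):
        days = [make_day(np.full(MINUTES_PER_DAY, 100.0)) for _ in range(n_valid)]
        days += [make_day(np.zeros(MINUTES_PER_DAY)) for _ in range(n_invalid)]
        return MinuteSeries("S1", days)

    @pytest.mark.parametrize("n_valid,included", [(3, True), (2, False), (14, True)])
    def test_min_valid_days(self, n_valid, included):
        result = include_subject(self._series_with_valid_days(n_valid))
        if included:
            assert isinstance(result, CleanSeries) and result.n_valid == n_valid
        else:
            assert isinstance(result, Exclusion)
            assert result.reason == "insufficient valid days"

    def test_empty_series_reason(self):
        result = include_subject(MinuteSeries("S1", []))
        assert isinstance(result, Exclusion) and result.reason == "never returned"


class TestFullPipeline:
    def test_idempotence(self, pms_params):
        series, _ = simulate_subject(pms_params, 5, seed=11)
        once, _ = preprocess_series(series)
        assert isinstance(once, CleanSeries)
        again, _ = preprocess_series(MinuteSeries(once.subject_id, once.valid_days))
        assert isinstance(again, CleanSeries)
        assert again.n_valid == once.n_valid
        assert np.array_equal(again.counts_matrix(), once.counts_matrix())
        assert np.array_equal(again.wear_matrix(), once.wear_matrix())

    def test_csv_roundtrip(self, pms_params, tmp_path):
        series, _ = simulate_subject(pms_params, 3, seed=13)
        write_counts_csv([series], tmp_path / "counts.csv")
        back = read_counts_csv(tmp_path / "counts.csv")
        assert len(back) == 1
        assert np.allclose(back[0].counts_matrix(), series.counts_matrix(), equal_nan=True)
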