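"""Nonwear detection, valid-day marking, DST resolution and subject inclusion.

Rules applied, in order:

1. nonwear: every maximal run of >= 90 consecutive zero-count minutes is
   flagged nonwear.  Runs are found on the subject's concatenated series so a
   removal episode straddling midnight is still caught, then mapped back to
   days.
2. valid day: >= 1296 wear minutes (90% of the day).
3. daylight-saving resolution: a spring-forward transition leaves one hour
   missing, imputed minute-wise from the mean of the same minute-of-day over
   the subject's other valid days; a fall-back transition duplicates an hour,
   resolved to the minute-wise mean of the two copies, and leaves the final
   day one hour short, imputed the same way.  Imputed minutes count as wear.
4. inclusion: subjects need >= 3 valid days; others are excluded with a
   logged reason.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MINUTES_PER_DAY,
    MIN_VALID_DAYS,
    NONWEAR_RUN_MIN,
    VALID_DAY_WEAR_MIN,
    CleanSeries,
    DayRecord,
    Exclusion,
    MinuteSeries,
)

__all__ = [
    "nonwear_mask",
    "detect_nonwear",
    "detect_nonwear_series",
    "mark_valid_day",
    "resolve_dst",
    "include_subject",
    "preprocess_series",
    "preprocess_cohort",
    "read_counts_csv",
    "read_epoch_csv",
    "write_exclusions",
]


def nonwear_mask(counts: np.ndarray, min_len: int = NONWEAR_RUN_MIN) -> np.ndarray:
    """Wear flags for a 1-D count vector.

    Minutes inside a maximal run of zeros of length >= ``min_len`` are
    nonwear; all other observed minutes are wear.  Missing minutes (NaN) are
    not wear and break zero runs (a gap is not evidence of zeros).
    """
    counts = np.asarray(counts, dtype=float)
    wear = ~np.isnan(counts)
    is_zero = np.zeros(counts.shape, dtype=bool)
    is_zero[wear] = counts[wear] == 0
    if not is_zero.any():
        return wear
    # run-length encode the zero indicator
    padded = np.concatenate([[False], is_zero, [False]])
    change = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = change[::2], change[1::2]
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            wear[s:e] = False
    return wear


def detect_nonwear(day: DayRecord) -> DayRecord:
    """Apply the zero-run nonwear rule to a single day in isolation."""
    out = day.copy()
    out.wear = nonwear_mask(out.counts)
    return out


def detect_nonwear_series(series: MinuteSeries) -> MinuteSeries:
    """Apply the nonwear rule on the concatenated series (runs may span midnight)."""
    out = series.copy()
    if not out.days:
        return out
    flat = np.concatenate([d.counts for d in out.days])
    wear = nonwear_mask(flat)
    for i, day in enumerate(out.days):
        day.wear = wear[i * MINUTES_PER_DAY : (i + 1) * MINUTES_PER_DAY]
    return out


def mark_valid_day(day: DayRecord) -> DayRecord:
    out = day.copy()
    out.valid = out.wear_minutes >= VALID_DAY_WEAR_MIN
    return out


def _impute_from_valid_days(series: MinuteSeries, day_idx: int) -> bool:
    """Fill a day's missing minutes with the minute-of-day mean over the
    subject's *other* valid days.  Returns False when no source day exists."""
    day = series.days[day_idx]
    missing = np.isnan(day.counts)
    if not missing.any():
        return True
    sources = [
        d.counts for i, d in enumerate(series.days) if i != day_idx and d.valid
    ]
    if not sources:
        return False
    src = np.vstack(sources)
    with np.errstate(invalid="ignore"):
        minute_mean = np.nanmean(src, axis=0)
    fillable = missing & ~np.isnan(minute_mean)
    day.counts[fillable] = minute_mean[fillable]
    day.imputed = day.imputed | fillable
    day.wear[fillable] = True
    return not np.isnan(day.counts).any()


def resolve_dst(series: MinuteSeries) -> tuple[MinuteSeries, list[str]]:
    """Resolve daylight-saving artifacts; returns (series, flags).

    Duplicated hours (fall-back) are replaced by the minute-wise mean of the
    two copies.  Missing minutes (spring-forward skipped hour, or the short
    final day after a fall-back) are imputed from other valid days.  A flag
    string is recorded per day that could not be fully resolved.
    """
    out = series.copy()
    flags: list[str] = []
    for day in out.days:
        if day.duplicate is not None:
            start, second = day.duplicate
            first = day.counts[start : start + len(second)]
            both = np.vstack([first, second])
            with np.errstate(invalid="ignore"):
                day.counts[start : start + len(second)] = np.nanmean(both, axis=0)
            day.wear[start : start + len(second)] = ~np.isnan(
                day.counts[start : start + len(second)]
            )
            day.duplicate = None
    for idx, day in enumerate(out.days):
        if np.isnan(day.counts).any():
            if not _impute_from_valid_days(out, idx):
                flags.append(
                    f"{out.subject_id}: day {idx} has unresolvable missing minutes"
                )
            # imputation may change the wear count, so revisit validity
            day.valid = day.wear_minutes >= VALID_DAY_WEAR_MIN
    return out, flags


def include_subject(series: MinuteSeries) -> CleanSeries | Exclusion:
    """Keep subjects with >= 3 valid days; otherwise return an Exclusion."""
    valid = [d for d in series.days if d.valid]
    if len(valid) < MIN_VALID_DAYS:
        reason = "never returned" if not series.days else "insufficient valid days"
        return Exclusion(series.subject_id, reason, n_valid=len(valid))
    return CleanSeries(series.subject_id, valid)


def preprocess_series(series: MinuteSeries) -> tuple[CleanSeries | Exclusion, list[str]]:
    """Full preprocessing for one subject: nonwear -> valid days -> DST -> inclusion.

    Idempotent: feeding the surviving days back through produces the same
    result, since all flags are recomputed deterministically from counts.
    """
    s = detect_nonwear_series(series)
    s.days = [mark_valid_day(d) for d in s.days]
    s, flags = resolve_dst(s)
    # imputation introduced new observed values; recompute wear and validity
    s = detect_nonwear_series(s)
    for day in s.days:
        day.valid = day.wear_minutes >= VALID_DAY_WEAR_MIN
    return include_subject(s), flags


def preprocess_cohort(
    series_list: list[MinuteSeries],
) -> tuple[list[CleanSeries], list[Exclusion], list[str]]:
    cleans: list[CleanSeries] = []
    exclusions: list[Exclusion] = []
    flags: list[str] = []
    for series in series_list:
        result, f = preprocess_series(series)
        flags.extend(f)
        if isinstance(result, Exclusion):
            exclusions.append(result)
        else:
            cleans.append(result)
    return cleans, exclusions, flags


# ---------------------------------------------------------------------------
# I/O


def read_counts_csv(path: str | Path) -> list[MinuteSeries]:
    """Read the minute-level CSV written by the synthetic generator.

    Columns: subject_id, date, minute_of_day, count, wear.  An empty count
    field is a missing minute.  The wear column is advisory (the generator's
    truth); wear flags are always recomputed by preprocessing.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    out: list[MinuteSeries] = []
    for sid, sdf in df.groupby("subject_id", sort=True):
        days: list[DayRecord] = []
        for date, ddf in sdf.groupby("date", sort=True):
            counts = np.full(MINUTES_PER_DAY, np.nan)
            mins = ddf["minute_of_day"].to_numpy(dtype=int)
            counts[mins] = ddf["count"].to_numpy(dtype=float)
            days.append(DayRecord(date=pd.Timestamp(date).date(), counts=counts))
        out.append(MinuteSeries(str(sid), days))
    return out


def read_epoch_csv(path: str | Path, subject_id: str | None = None) -> list[MinuteSeries]:
    """Read a long-format epoch export with (subject_id?, timestamp, count).

    Timestamps are binned to minute-of-day on their calendar date; minutes
    with no row are missing.
    """
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["timestamp"])
    df = df.assign(
        _date=ts.dt.date, _minute=ts.dt.hour * 60 + ts.dt.minute
    )
    if "subject_id" not in df.columns:
        df["subject_id"] = subject_id if subject_id is not None else "subject"
    out: list[MinuteSeries] = []
    for sid, sdf in df.groupby("subject_id", sort=True):
        days = []
        for date, ddf in sdf.groupby("_date", sort=True):
            counts = np.full(MINUTES_PER_DAY, np.nan)
            counts[ddf["_minute"].to_numpy(dtype=int)] = ddf["count"].to_numpy(
                dtype=float
            )
            days.append(DayRecord(date=date, counts=counts))
        out.append(MinuteSeries(str(sid), days))
    return out


def write_exclusions(exclusions: list[Exclusion], path: str | Path) -> None:
    payload = [
        {"subject_id": e.subject_id, "reason": e.reason, "n_valid": e.n_valid}
        for e in exclusions
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
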