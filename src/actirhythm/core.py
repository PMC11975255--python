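"""Shared data containers for minute-epoch wrist actigraphy analysis.

The pipeline's substrate is the minute-epoch vector-magnitude activity count:
each subject contributes a stack of calendar days, each day holding 1440
minute slots (midnight to 23:59).  Counts are nonnegative; a minute may be
*missing* (e.g. the hour skipped by a spring-forward clock change), which is
distinct from a zero count ("no movement") and from *nonwear* (device off the
wrist, detected downstream from long zero runs).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

MINUTES_PER_DAY = 1440

#: Minimum wear minutes for a day to count as valid (>= 90% of 1440).
VALID_DAY_WEAR_MIN = 1296

#: Minimum number of valid days for a subject to enter the analysis.
MIN_VALID_DAYS = 3

#: Minimum zero-run length (minutes) declared nonwear.
NONWEAR_RUN_MIN = 90


@dataclass
class DayRecord:
    """One calendar day of minute-epoch counts.

    ``counts`` is a float vector of length 1440 with NaN marking missing
    minutes.  ``wear`` flags minutes during which the device is considered
    worn.  ``duplicate`` optionally stores the second copy of an hour repeated
    by a fall-back daylight-saving transition as ``(start_minute, values)``;
    it is consumed (averaged into ``counts``) by DST resolution.
    """

    date: dt.date
    counts: np.ndarray
    wear: np.ndarray | None = None
    valid: bool = False
    imputed: np.ndarray | None = None
    duplicate: tuple[int, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (MINUTES_PER_DAY,):
            raise ValueError(
                f"day must hold exactly {MINUTES_PER_DAY} minute slots, "
                f"got {self.counts.shape}"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.counts < 0):
                raise ValueError("activity counts must be nonnegative")
        if self.wear is None:
            self.wear = ~np.isnan(self.counts)
        self.wear = np.asarray(self.wear, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros(MINUTES_PER_DAY, dtype=bool)

    @property
    def wear_minutes(self) -> int:
        return int(np.sum(self.wear))

    @property
    def n_observed(self) -> int:
        """Observed minute-values including any duplicated DST hour."""
        n = int(np.sum(~np.isnan(self.counts)))
        if self.duplicate is not None:
            n += int(np.sum(~np.isnan(self.duplicate[1])))
        return n

    def copy(self) -> "DayRecord":
        dup = None
        if self.duplicate is not None:
            dup = (self.duplicate[0], self.duplicate[1].copy())
        return DayRecord(
            date=self.date,
            counts=self.counts.copy(),
            wear=self.wear.copy(),
            valid=self.valid,
            imputed=self.imputed.copy(),
            duplicate=dup,
        )


@dataclass
class MinuteSeries:
    """A subject's full worn period: an ordered stack of DayRecords."""

    subject_id: str
    days: list[DayRecord] = field(default_factory=list)

    @property
    def n_days(self) -> int:
        return len(self.days)

    def counts_matrix(self) -> np.ndarray:
        """(n_days, 1440) float matrix of counts, NaN where missing."""
        return np.vstack([d.counts for d in self.days])

    def wear_matrix(self) -> np.ndarray:
        return np.vstack([d.wear for d in self.days])

    def copy(self) -> "MinuteSeries":
        return MinuteSeries(self.subject_id, [d.copy() for d in self.days])


@dataclass
class CleanSeries:
    """Preprocessed subject series retaining only valid days."""

    subject_id: str
    valid_days: list[DayRecord]

    @property
    def n_valid(self) -> int:
        return len(self.valid_days)

    def counts_matrix(self) -> np.ndarray:
        return np.vstack([d.counts for d in self.valid_days])

    def wear_matrix(self) -> np.ndarray:
        return np.vstack([d.wear for d in self.valid_days])


@dataclass
class Exclusion:
    """Record of a subject dropped by the inclusion rules."""

    subject_id: str
    reason: str
    n_valid: int = 0


@dataclass
class SubjectRecord:
    """Covariates and self-report for one subject."""

    subject_id: str
    group: str
    age: float
    sex: str
    bmi: float
    ipaq_met_min: float | None = None
    ipaq_category: str | None = None


@dataclass(frozen=True)
class CutPoints:
    """Count thresholds separating nonactive / LIPA / MVPA minutes.

    Reference values: a minute is nonactive when count <= 2000, MVPA when
    count > 6750, LIPA in between.
    """

    nonactive_max: float = 2000.0
    mvpa_min: float = 6750.0

    def __post_init__(self) -> None:
        if not (0 < self.nonactive_max < self.mvpa_min):
            raise ValueError("require 0 < nonactive_max < mvpa_min")
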