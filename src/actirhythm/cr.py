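"""Circadian / diurnal rest-activity metrics.

Per subject, from valid days only:

* M10 / L5 landmarks: mean activity in the most active 10-hour and least
  active 5-hour circular windows of the mean diurnal profile, with window
  midpoints as clock times; relative amplitude RA = (M10-L5)/(M10+L5).
* DARE: proportion of 24-h activity in a daytime window (default 08:00-20:00).
* Cosinor MESOR / amplitude / acrophase, fitted on minute-level data pooled
  over valid days.
* Nonparametric IV (intradaily variability, hour-to-hour fragmentation) and
  IS (interdaily stability, day-to-day constancy), on hourly means.

Landmark metrics are computed on the raw count scale by default (reported
group magnitudes are count-scale); pass ``log_scale=True`` to use
log(1+count) instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import MINUTES_PER_DAY, CleanSeries
from .cosinor import Cosinor

__all__ = ["CRFeatures", "mean_profile", "m10_l5", "dare", "iv_is", "aggregate_cr"]


@dataclass
class CRFeatures:
    subject_id: str
    m10: float
    m10_mid: float          # clock hours of the window center
    l5: float
    l5_mid: float
    ra: float
    dare: float
    mesor: float
    amplitude: float
    acrophase: float
    iv: float
    is_: float

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "M10": self.m10,
            "Mid_M10": self.m10_mid,
            "L5": self.l5,
            "Mid_L5": self.l5_mid,
            "RA": self.ra,
            "DARE": self.dare,
            "MESOR": self.mesor,
            "Amplitude": self.amplitude,
            "Acrophase": self.acrophase,
            "IV": self.iv,
            "IS": self.is_,
        }


def mean_profile(clean: CleanSeries) -> np.ndarray:
    """Minute-of-day mean over valid days, nonwear minutes treated as missing.

    Minutes unobserved on every valid day are filled by circular linear
    interpolation so downstream window searches see a complete profile.
    """
    counts = clean.counts_matrix().copy()
    counts[~clean.wear_matrix()] = np.nan
    if np.all(np.isnan(counts)):
        raise ValueError(f"{clean.subject_id}: profile has no observed minutes")
    with np.errstate(invalid="ignore"):
        prof = np.nanmean(counts, axis=0)
    bad = np.isnan(prof)
    if bad.any():
        idx = np.arange(MINUTES_PER_DAY)
        good = ~bad
        # circular interpolation: extend the observed support by one period
        xp = np.concatenate([idx[good], idx[good] + MINUTES_PER_DAY])
        fp = np.concatenate([prof[good], prof[good]])
        prof[bad] = np.interp(idx[bad] + MINUTES_PER_DAY, xp, fp)
    return prof


def _circular_window_means(profile: np.ndarray, width: int) -> np.ndarray:
    """Mean of every circular window [i, i+width) of a 1440-vector."""
    ext = np.concatenate([profile, profile[: width - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    return (csum[width:] - csum[:-width]) / width


def m10_l5(profile: np.ndarray) -> tuple[float, float, float, float, float]:
    """Most-active-10h / least-active-5h landmarks of a diurnal profile.

    Windows are circular (may wrap midnight).  Ties are broken toward the
    earliest window start.  Returns (m10, m10_mid, l5, l5_mid, ra) with
    midpoints as clock hours.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (MINUTES_PER_DAY,):
        raise ValueError("profile must hold 1440 minutes")
    if np.isnan(profile).any():
        raise ValueError("profile must be complete (impute upstream)")
    w10 = _circular_window_means(profile, 600)
    w5 = _circular_window_means(profile, 300)
    i10 = int(np.argmax(w10))
    i5 = int(np.argmin(w5))
    m10 = float(w10[i10])
    l5 = float(w5[i5])
    m10_mid = ((i10 + 600 / 2) % MINUTES_PER_DAY) / 60.0
    l5_mid = ((i5 + 300 / 2) % MINUTES_PER_DAY) / 60.0
    denom = m10 + l5
    ra = (m10 - l5) / denom if denom > 0 else float("nan")
    return m10, m10_mid, l5, l5_mid, ra


def dare(profile: np.ndarray, window: tuple[float, float] = (8.0, 20.0)) -> float:
    """Daytime activity ratio estimate: in-window activity over the 24-h total."""
    profile = np.asarray(profile, dtype=float)
    total = float(np.sum(profile))
    if total <= 0:
        raise ValueError("profile carries no activity; DARE undefined")
    hour = np.arange(MINUTES_PER_DAY) / 60.0
    start, end = window
    mask = (hour >= start) & (hour < end) if start <= end else (hour >= start) | (hour < end)
    return float(np.sum(profile[mask]) / total)


def iv_is(hourly: np.ndarray) -> tuple[float, float]:
    """Intradaily variability and interdaily stability from hourly means.

    ``hourly`` is (n_days, 24) — missing hours NaN.  With N observed hours
    x_i, hour-of-day means x̄_h (p=24) and grand mean x̄:

        IV = N * Σ_{i=2..N} (x_i - x_{i-1})^2 / ((N-1) * Σ_i (x_i - x̄)^2)
        IS = N * Σ_h (x̄_h - x̄)^2 / (p * Σ_i (x_i - x̄)^2)

    Successive differences skip pairs with a missing member.
    """
    hourly = np.asarray(hourly, dtype=float)
    if hourly.ndim != 2 or hourly.shape[1] != 24:
        raise ValueError("hourly must be (n_days, 24)")
    if hourly.shape[0] < 2:
        raise ValueError("IV/IS need >= 2 days of hourly data")
    flat = hourly.reshape(-1)
    obs = ~np.isnan(flat)
    x = flat[obs]
    n = x.size
    grand = float(np.mean(x))
    ss = float(np.sum((x - grand) ** 2))
    if ss == 0:
        raise ValueError("zero variance; IV/IS undefined")
    d = np.diff(flat)
    pair_ok = obs[1:] & obs[:-1]
    msd = float(np.sum(d[pair_ok] ** 2))
    iv = n * msd / ((n - 1) * ss)
    with np.errstate(invalid="ignore"):
        hmeans = np.nanmean(hourly, axis=0)
    hmeans = hmeans[~np.isnan(hmeans)]
    p = hmeans.size
    is_ = n * float(np.sum((hmeans - grand) ** 2)) / (p * ss)
    return float(iv), float(is_)


def hourly_means(clean: CleanSeries) -> np.ndarray:
    """(n_valid, 24) mean count per (day, hour) over wear minutes."""
    counts = clean.counts_matrix().copy()
    counts[~clean.wear_matrix()] = np.nan
    binned = counts.reshape(clean.n_valid, 24, 60)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN hour -> NaN
        return np.nanmean(binned, axis=2)


def aggregate_cr(
    clean: CleanSeries,
    dare_window: tuple[float, float] = (8.0, 20.0),
    log_scale: bool = False,
) -> CRFeatures:
    """All circadian metrics for one preprocessed subject."""
    prof = mean_profile(clean)
    if log_scale:
        prof = np.log1p(prof)
    m10, m10_mid, l5, l5_mid, ra = m10_l5(prof)
    d = dare(prof, window=dare_window)

    counts = clean.counts_matrix()
    wear = clean.wear_matrix()
    vals = counts[wear]
    if log_scale:
        vals = np.log1p(vals)
    minute_of_day = np.tile(np.arange(MINUTES_PER_DAY), (clean.n_valid, 1))
    hrs = minute_of_day[wear] / 60.0
    res = Cosinor(vals, hrs).fit()

    hourly = hourly_means(clean)
    if log_scale:
        hourly = np.log1p(hourly)
    iv, is_ = iv_is(hourly)

    return CRFeatures(
        subject_id=clean.subject_id,
        m10=m10,
        m10_mid=m10_mid,
        l5=l5,
        l5_mid=l5_mid,
        ra=ra,
        dare=d,
        mesor=res.mesor,
        amplitude=res.amplitude,
        acrophase=res.acrophase,
        iv=iv,
        is_=is_,
    )
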