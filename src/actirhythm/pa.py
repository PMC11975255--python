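"""Physical-activity volume, intensity, composition and fragmentation metrics.

Per valid day, over wear minutes only:

* TAC: total activity counts; TLAC: total log(1+count); 2-hour TAC bins.
* Intensity minutes (nonactive / LIPA / MVPA) from count cut points.
* Fragmentation: with minutes dichotomized active (count > nonactive cut)
  vs sedentary, ASTP = active->sedentary transitions per active minute and
  SATP = sedentary->active transitions per sedentary minute.  Transitions are
  only counted between consecutive wear minutes — a nonwear gap breaks a bout
  without fabricating a transition, and the day's final bout is censored.

Subject-level features average each daily metric over valid days; the
composition ratios are formed from the averaged minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MINUTES_PER_DAY, CleanSeries, CutPoints, DayRecord
from .calibration import classify_minutes

__all__ = ["PAFeatures", "daily_volume", "fragmentation", "aggregate_pa", "TAC_2H_NAMES"]

TAC_2H_NAMES = [f"TAC_{h:02d}_{h + 2:02d}" for h in range(0, 24, 2)]


@dataclass
class PAFeatures:
    subject_id: str
    tac: float
    tlac: float
    nonactive_min: float
    lipa_min: float
    mvpa_min: float
    mvpa_over_lipa: float
    mvpa_over_nonactive: float
    lipa_over_nonactive: float
    satp: float
    astp: float
    tac_2h: np.ndarray = field(default_factory=lambda: np.zeros(12))

    def as_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "TAC": self.tac,
            "TLAC": self.tlac,
            "Nonactive": self.nonactive_min,
            "LIPA": self.lipa_min,
            "MVPA": self.mvpa_min,
            "MVPA_LIPA": self.mvpa_over_lipa,
            "MVPA_Nonactive": self.mvpa_over_nonactive,
            "LIPA_Nonactive": self.lipa_over_nonactive,
            "SATP": self.satp,
            "ASTP": self.astp,
        }
        d.update(dict(zip(TAC_2H_NAMES, self.tac_2h)))
        return d


def daily_volume(day: DayRecord, cp: CutPoints) -> dict:
    """Volume / intensity / temporal-local metrics for one valid day."""
    if not day.valid:
        raise ValueError("daily metrics are defined for valid days only")
    wear = day.wear
    counts = np.where(wear, day.counts, np.nan)
    obs = counts[wear]
    tac = float(np.sum(obs))
    tlac = float(np.sum(np.log1p(obs)))
    cls = classify_minutes(counts, cp)
    nonactive = float(np.sum(cls == 0))
    lipa = float(np.sum(cls == 1))
    mvpa = float(np.sum(cls == 2))
    binned = np.where(wear, day.counts, 0.0).reshape(12, 120)
    tac_2h = binned.sum(axis=1)
    return {
        "tac": tac,
        "tlac": tlac,
        "nonactive_min": nonactive,
        "lipa_min": lipa,
        "mvpa_min": mvpa,
        "tac_2h": tac_2h,
    }


def fragmentation_binary(active: np.ndarray, wear: np.ndarray | None = None) -> tuple[float, float]:
    """(satp, astp) from a binary active(1)/sedentary(0) minute sequence.

    ``wear`` masks minutes contributing states; transitions count only
    between consecutive wear minutes.  Undefined rates (no minutes in the
    source state) are NaN.
    """
    active = np.asarray(active, dtype=bool)
    if wear is None:
        wear = np.ones(active.shape, dtype=bool)
    wear = np.asarray(wear, dtype=bool)
    pair = wear[:-1] & wear[1:]
    a0, a1 = active[:-1], active[1:]
    as_trans = int(np.sum(pair & a0 & ~a1))
    sa_trans = int(np.sum(pair & ~a0 & a1))
    n_active = int(np.sum(active & wear))
    n_sed = int(np.sum(~active & wear))
    astp = as_trans / n_active if n_active > 0 else float("nan")
    satp = sa_trans / n_sed if n_sed > 0 else float("nan")
    return satp, astp


def fragmentation(day: DayRecord, cp: CutPoints) -> tuple[float, float]:
    """(satp, astp) for one valid day, dichotomized at the nonactive cut."""
    if not day.valid:
        raise ValueError("fragmentation is defined for valid days only")
    active = np.zeros(MINUTES_PER_DAY, dtype=bool)
    active[day.wear] = day.counts[day.wear] > cp.nonactive_max
    return fragmentation_binary(active, day.wear)


def aggregate_pa(clean: CleanSeries, cp: CutPoints) -> PAFeatures:
    """Subject-level PA features: daily metrics averaged over valid days.

    Days with undefined fragmentation (no active or no sedentary minutes)
    drop out of the corresponding average; composition ratios are formed
    from the averaged intensity minutes.
    """
    dailies = [daily_volume(d, cp) for d in clean.valid_days]
    frags = [fragmentation(d, cp) for d in clean.valid_days]
    tac = float(np.mean([d["tac"] for d in dailies]))
    tlac = float(np.mean([d["tlac"] for d in dailies]))
    nonactive = float(np.mean([d["nonactive_min"] for d in dailies]))
    lipa = float(np.mean([d["lipa_min"] for d in dailies]))
    mvpa = float(np.mean([d["mvpa_min"] for d in dailies]))
    tac_2h = np.mean([d["tac_2h"] for d in dailies], axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all days undefined -> NaN
        satp = float(np.nanmean([f[0] for f in frags]))
        astp = float(np.nanmean([f[1] for f in frags]))

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    return PAFeatures(
        subject_id=clean.subject_id,
        tac=tac,
        tlac=tlac,
        nonactive_min=nonactive,
        lipa_min=lipa,
        mvpa_min=mvpa,
        mvpa_over_lipa=ratio(mvpa, lipa),
        mvpa_over_nonactive=ratio(mvpa, nonactive),
        lipa_over_nonactive=ratio(lipa, nonactive),
        satp=satp,
        astp=astp,
        tac_2h=tac_2h,
    )
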