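"""Intensity cut points and their cohort-specific calibration.

Minutes are classed nonactive (count <= nonactive_max), LIPA
(nonactive_max < count <= mvpa_min) or MVPA (count > mvpa_min); reference
thresholds 2000 and 6750 counts.  ``calibrate`` searches a grid of threshold
pairs for the one whose accelerometry-derived activity estimates agree best
with self-reported activity (IPAQ), the concordance statistic being the mean
of (a) the Spearman correlation between MVPA min/day and IPAQ MET-min/week
and (b) the linear-weighted kappa between tertiles of the two.  Calibration
is optional — the pipeline runs with the reference pair by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .core import CleanSeries, CutPoints, SubjectRecord

__all__ = [
    "CutPoints",
    "classify_minute",
    "classify_minutes",
    "CalibrationResult",
    "calibrate",
    "default_grid",
]

#: Integer codes used by classify_minutes.
NONACTIVE, LIPA, MVPA = 0, 1, 2
_CLASS_NAMES = {NONACTIVE: "nonactive", LIPA: "LIPA", MVPA: "MVPA"}


def classify_minutes(counts: np.ndarray, cp: CutPoints) -> np.ndarray:
    """Vectorized minute classification: 0 nonactive, 1 LIPA, 2 MVPA, -1 missing."""
    counts = np.asarray(counts, dtype=float)
    out = np.full(counts.shape, -1, dtype=np.int8)
    obs = ~np.isnan(counts)
    out[obs & (counts <= cp.nonactive_max)] = NONACTIVE
    out[obs & (counts > cp.nonactive_max) & (counts <= cp.mvpa_min)] = LIPA
    out[obs & (counts > cp.mvpa_min)] = MVPA
    return out


def classify_minute(count: float, cp: CutPoints) -> str | None:
    """Class label for a single minute count; None when the count is missing."""
    code = int(classify_minutes(np.array([count]), cp)[0])
    return None if code == -1 else _CLASS_NAMES[code]


def default_grid() -> tuple[np.ndarray, np.ndarray]:
    """Threshold grid spanning published wrist cut points."""
    return (
        np.arange(500, 4000 + 1, 250, dtype=float),
        np.arange(4000, 10000 + 1, 250, dtype=float),
    )


@dataclass
class CalibrationResult:
    cutpoints: CutPoints
    concordance: float
    grid: list[tuple[float, float, float]]  # (nonactive_max, mvpa_min, concordance)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "nonactive_max": self.cutpoints.nonactive_max,
                    "mvpa_min": self.cutpoints.mvpa_min,
                    "concordance": self.concordance,
                    "grid": [
                        {"nonactive_max": a, "mvpa_min": b, "concordance": c}
                        for a, b, c in self.grid
                    ],
                },
                indent=2,
            )
        )


def _tertiles(x: np.ndarray) -> np.ndarray:
    q = np.quantile(x, [1 / 3, 2 / 3])
    return np.digitize(x, q)


def _concordance(mvpa_per_day: np.ndarray, ipaq: np.ndarray) -> float:
    rho = stats.spearmanr(mvpa_per_day, ipaq).statistic
    if np.isnan(rho):  # constant MVPA vector at an extreme threshold
        rho = 0.0
    ta, tb = _tertiles(mvpa_per_day), _tertiles(ipaq)
    if np.unique(ta).size < 2:
        kappa = 0.0
    else:
        kappa = cohen_kappa_score(ta, tb, weights="linear")
    return float((rho + kappa) / 2.0)


def calibrate(
    cohort: list[CleanSeries],
    records: list[SubjectRecord],
    grid_spec: tuple[np.ndarray, np.ndarray] | None = None,
    reference: CutPoints = CutPoints(),
) -> CalibrationResult:
    """Exhaustive grid search for the concordance-maximizing cut-point pair.

    Ties at the maximum are broken toward the pair closest (Euclidean) to the
    reference pair.  Raises on degenerate (constant) IPAQ, where concordance
    is undefined.
    """
    rec_by_id = {r.subject_id: r for r in records}
    ipaq = np.array([rec_by_id[c.subject_id].ipaq_met_min for c in cohort], dtype=float)
    if np.isnan(ipaq).any():
        raise ValueError("every subject needs an IPAQ summary for calibration")
    if np.ptp(ipaq) == 0:
        raise ValueError("degenerate IPAQ (all identical); concordance undefined")

    # sorted wear-minute counts per subject: minutes above any threshold via
    # a single searchsorted, so the grid sweep is O(grid * n log m)
    sorted_counts = []
    n_days = []
    for c in cohort:
        counts = c.counts_matrix()
        wear = c.wear_matrix()
        sorted_counts.append(np.sort(counts[wear]))
        n_days.append(c.n_valid)
    n_days_arr = np.array(n_days, dtype=float)

    def mvpa_per_day(threshold: float) -> np.ndarray:
        above = np.array(
            [sc.size - np.searchsorted(sc, threshold, side="right") for sc in sorted_counts],
            dtype=float,
        )
        return above / n_days_arr

    na_grid, mv_grid = grid_spec if grid_spec is not None else default_grid()
    # the statistic depends on the MVPA threshold only; evaluate once per
    # mvpa_min and replicate across nonactive_max
    conc_by_mv = {float(mv): _concordance(mvpa_per_day(mv), ipaq) for mv in mv_grid}
    grid_eval = [
        (float(na), float(mv), conc_by_mv[float(mv)])
        for na in na_grid
        for mv in mv_grid
        if na < mv
    ]
    if not grid_eval:
        raise ValueError("empty grid (no pair with nonactive_max < mvpa_min)")
    best = max(c for _, _, c in grid_eval)
    contenders = [(na, mv) for na, mv, c in grid_eval if c == best]
    ref = (reference.nonactive_max, reference.mvpa_min)
    na, mv = min(
        contenders, key=lambda p: ((p[0] - ref[0]) ** 2 + (p[1] - ref[1]) ** 2, p)
    )
    return CalibrationResult(CutPoints(na, mv), best, grid_eval)
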