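"""Group comparisons and covariate-adjusted logistic association models.

Three surfaces:

* descriptive group comparisons (Welch t test for continuous metrics,
  Pearson chi-square for categorical), combined RRMS vs PMS;
* per-metric logistic regressions of a binary group contrast on one metric
  plus age, sex and BMI, with Wald 95% CIs; TAC and TLAC are divided by
  their sample SD before entry, other metrics enter on their native scale;
* the M10-window sensitivity analysis: PA metrics recomputed inside each
  subject's most-active-10-hour window, then the same models rerun.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .core import MINUTES_PER_DAY, CleanSeries, CutPoints
from .calibration import classify_minutes
from .cr import mean_profile
from .pa import fragmentation_binary

__all__ = [
    "ModelResult",
    "group_compare",
    "fit_logistic",
    "associate_metrics",
    "m10_sensitivity",
    "CONTRAST_PMS_VS_RRMS",
    "CONTRAST_SUSPECTED_VS_STABLE",
]

#: (name, case groups, reference groups)
CONTRAST_PMS_VS_RRMS = ("PMS_vs_RRMS", ("PMS",), ("RRMS-Stable", "RRMS-Suspected"))
CONTRAST_SUSPECTED_VS_STABLE = (
    "Suspected_vs_Stable",
    ("RRMS-Suspected",),
    ("RRMS-Stable",),
)

#: Metrics divided by their sample SD before model entry.
SD_SCALED_METRICS = ("TAC", "TLAC")


@dataclass
class ModelResult:
    predictor: str
    estimate: float           # log-odds per predictor unit
    ci_low: float
    ci_high: float
    p: float
    scaling_note: str = ""
    separation: bool = False

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "scaling_note": self.scaling_note,
        }


def group_compare(
    features: pd.DataFrame,
    records: pd.DataFrame,
    case_groups: tuple[str, ...] = ("PMS",),
    ref_groups: tuple[str, ...] = ("RRMS-Stable", "RRMS-Suspected"),
    welch: bool = True,
) -> pd.DataFrame:
    """Per-column two-group tests: t test (continuous) or chi-square (categorical).

    ``features`` is indexed by subject_id; ``records`` must carry a ``group``
    column on the same index.
    """
    grp = records.loc[features.index, "group"]
    in_case = grp.isin(case_groups).to_numpy()
    in_ref = grp.isin(ref_groups).to_numpy()
    if in_case.sum() < 2 or in_ref.sum() < 2:
        raise ValueError("need >= 2 subjects per compared group")
    rows = []
    for col in features.columns:
        x = features[col]
        if pd.api.types.is_numeric_dtype(x):
            a = x[in_case].dropna().to_numpy(dtype=float)
            b = x[in_ref].dropna().to_numpy(dtype=float)
            if np.ptp(np.concatenate([a, b])) == 0:
                raise ValueError(f"{col}: constant across all subjects; test undefined")
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
            rows.append(
                {
                    "metric": col,
                    "test": "welch_t" if welch else "t",
                    "case_mean": a.mean(),
                    "case_sd": a.std(ddof=1),
                    "ref_mean": b.mean(),
                    "ref_sd": b.std(ddof=1),
                    "statistic": float(t),
                    "p": float(p),
                }
            )
        else:
            tab = pd.crosstab(np.where(in_case, "case", "ref"), x)
            chi2, p, _, _ = stats.chi2_contingency(tab)
            rows.append(
                {
                    "metric": col,
                    "test": "chi2",
                    "case_mean": np.nan,
                    "case_sd": np.nan,
                    "ref_mean": np.nan,
                    "ref_sd": np.nan,
                    "statistic": float(chi2),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows).set_index("metric")


def fit_logistic(
    outcome: np.ndarray,
    predictor: np.ndarray,
    covariates: pd.DataFrame | None = None,
    predictor_name: str = "x",
    scale_by_sd: bool = False,
) -> ModelResult:
    """Maximum-likelihood logistic fit of a binary outcome on one predictor.

    Returns the predictor's log-odds estimate with Wald 95% CI and two-sided
    p.  Perfect separation is flagged and refitted with a small L2 penalty
    (point estimate only; CI/p set to NaN).
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("outcome must contain both classes")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor; association undefined")
    note = ""
    if scale_by_sd:
        sd = float(np.std(x, ddof=1))
        x = x / sd
        note = f"predictor divided by its sample SD ({sd:.6g})"
    X = pd.DataFrame({predictor_name: x})
    if covariates is not None:
        cov = covariates.reset_index(drop=True).copy()
        for c in cov.columns:
            if not pd.api.types.is_numeric_dtype(cov[c]):
                cov[c] = pd.get_dummies(cov[c], drop_first=True, dtype=float).iloc[:, 0]
        X = pd.concat([X, cov], axis=1)
    X = sm.add_constant(X.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.isfinite(fit.bse[predictor_name]) or fit.bse[predictor_name] > 1e6:
            raise np.linalg.LinAlgError("unstable Wald SE")
        est = float(fit.params[predictor_name])
        ci = fit.conf_int().loc[predictor_name]
        return ModelResult(
            predictor_name, est, float(ci[0]), float(ci[1]),
            float(fit.pvalues[predictor_name]), note,
        )
    except (np.linalg.LinAlgError, PerfectSeparationError, PerfectSeparationWarning):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pen = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        return ModelResult(
            predictor_name,
            float(pen.params[predictor_name]),
            float("nan"),
            float("nan"),
            float("nan"),
            note + " [perfect separation: penalized point estimate]",
            separation=True,
        )


def associate_metrics(
    features: pd.DataFrame,
    records: pd.DataFrame,
    contrasts=(CONTRAST_PMS_VS_RRMS, CONTRAST_SUSPECTED_VS_STABLE),
    covariate_cols: tuple[str, ...] = ("age", "sex", "bmi"),
) -> pd.DataFrame:
    """Per-metric adjusted logistic models for each group contrast.

    Output mirrors the study's per-metric model table: one row per
    (metric, contrast) with estimate, Wald CI and p, plus a
    Benjamini-Hochberg column per contrast for transparency (the primary
    presentation is unadjusted per-metric p values).
    """
    rows = []
    for cname, case, ref in contrasts:
        keep = records["group"].isin(case + ref)
        rec = records.loc[keep]
        idx = features.index.intersection(rec.index)
        rec = rec.loc[idx]
        y = rec["group"].isin(case).to_numpy(dtype=float)
        cov = rec.loc[:, list(covariate_cols)]
        for col in features.columns:
            x = features.loc[idx, col].to_numpy(dtype=float)
            ok = ~np.isnan(x)
            try:
                res = fit_logistic(
                    y[ok],
                    x[ok],
                    cov.loc[ok],
                    predictor_name=col,
                    scale_by_sd=col in SD_SCALED_METRICS,
                )
                rows.append({"contrast": cname, **res.as_dict()})
            except ValueError as err:
                rows.append(
                    {
                        "contrast": cname,
                        "predictor": col,
                        "estimate": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": np.nan,
                        "scaling_note": f"not fit: {err}",
                    }
                )
    out = pd.DataFrame(rows)
    out["p_bh"] = np.nan
    for cname in out["contrast"].unique():
        mask = (out["contrast"] == cname) & out["p"].notna()
        out.loc[mask, "p_bh"] = _benjamini_hochberg(out.loc[mask, "p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _window_mask(start_minute: int, width: int) -> np.ndarray:
    mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
    idx = (start_minute + np.arange(width)) % MINUTES_PER_DAY
    mask[idx] = True
    return mask


def m10_sensitivity(
    cleans: list[CleanSeries], cp: CutPoints
) -> pd.DataFrame:
    """PA metrics recomputed inside each subject's M10 window.

    The window (600 minutes, circular) is located on the subject's mean
    diurnal profile; daily metrics are computed over wear minutes inside it
    and averaged over valid days.  Columns mirror the daily table with an
    ``M10_`` prefix.
    """
    rows = []
    for clean in cleans:
        prof = mean_profile(clean)
        w10 = _rolling_window_start(prof)
        mask = _window_mask(w10, 600)
        tacs, tlacs, nons, lipas, mvpas, satps, astps = [], [], [], [], [], [], []
        for day in clean.valid_days:
            wear = day.wear & mask
            obs = day.counts[wear]
            tacs.append(float(np.sum(obs)))
            tlacs.append(float(np.sum(np.log1p(obs))))
            cls = classify_minutes(np.where(wear, day.counts, np.nan), cp)
            nons.append(float(np.sum(cls == 0)))
            lipas.append(float(np.sum(cls == 1)))
            mvpas.append(float(np.sum(cls == 2)))
            active = np.zeros(MINUTES_PER_DAY, dtype=bool)
            active[wear] = day.counts[wear] > cp.nonactive_max
            s, a = fragmentation_binary(active, wear)
            satps.append(s)
            astps.append(a)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN fragmentation
            row = {
                "subject_id": clean.subject_id,
                "M10_TAC": float(np.mean(tacs)),
                "M10_TLAC": float(np.mean(tlacs)),
                "M10_Nonactive": float(np.mean(nons)),
                "M10_LIPA": float(np.mean(lipas)),
                "M10_MVPA": float(np.mean(mvpas)),
                "M10_SATP": float(np.nanmean(satps)),
                "M10_ASTP": float(np.nanmean(astps)),
            }
        mv, li, na = row["M10_MVPA"], row["M10_LIPA"], row["M10_Nonactive"]
        row["M10_MVPA_LIPA"] = mv / li if li > 0 else np.nan
        row["M10_MVPA_Nonactive"] = mv / na if na > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def _rolling_window_start(profile: np.ndarray, width: int = 600) -> int:
    ext = np.concatenate([profile, profile[: width - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    means = (csum[width:] - csum[:-width]) / width
    return int(np.argmax(means))
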