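"""Group tests, adjusted logistic models, M10-window sensitivity."""

import numpy as np
import pandas as pd
import pytest

from actirhythm.association import (
    associate_metrics,
    fit_logistic,
    group_compare,
    m10_sensitivity,
)
from actirhythm.core import MINUTES_PER_DAY, CutPoints
from actirhythm.pa import aggregate_pa

from conftest import make_clean


def log_odds_ratio(a, b, c, d):
    """Closed-form 2x2 oracle: log[(a*d)/(b*c)] for exposed/unexposed cases."""
    return np.log((a * d) / (b * c))


class TestFitLogistic:
    def test_single_binary_predictor_matches_2x2_oracle(self):
        # (a,b,c,d) = (10,20,30,5): cases with x=1, controls x=1, cases x=0, controls x=0
        a, b, c, d = 10, 20, 30, 5
        y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
        res = fit_logistic(y, x)
        assert res.estimate == pytest.approx(log_odds_ratio(a, b, c, d), abs=1e-6)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_rescaling_predictor_rescales_estimate(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = (rng.random(200) < 1 / (1 + np.exp(-x))).astype(float)
        r1 = fit_logistic(y, x)
        r10 = fit_logistic(y, 10 * x)
        assert r10.estimate == pytest.approx(r1.estimate / 10, rel=1e-6)
        assert r10.p == pytest.approx(r1.p, rel=1e-6)

    def test_sd_scaling_noted(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 5, 150)
        y = (rng.random(150) < 0.5).astype(float)
        res = fit_logistic(y, x, scale_by_sd=True)
        assert "SD" in res.scaling_note

    def test_constant_predictor_rejected(self):
        y = np.array([0.0, 1.0] * 10)
        with pytest.raises(ValueError):
            fit_logistic(y, np.ones(20))

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros(20), np.arange(20.0))

    def test_perfect_separation_flagged(self):
        y = np.concatenate([np.zeros(20), np.ones(20)])
        x = np.concatenate([np.arange(20.0), 100 + np.arange(20.0)])
        res = fit_logistic(y, x)
        assert res.separation
        assert np.isnan(res.p)

    def test_wald_ci_covers_null_at_nominal_rate(self):
        """Predictor independent of outcome: the 95% CI covers zero ~95% of
        the time (check within binomial error over 300 replicates)."""
        rng = np.random.default_rng(2)
        cover = 0
        n_rep = 300
        for _ in range(n_rep):
            x = rng.normal(0, 1, 120)
            y = (rng.random(120) < 0.5).astype(float)
            res = fit_logistic(y, x)
            cover += res.ci_low <= 0 <= res.ci_high
        rate = cover / n_rep
        assert abs(rate - 0.95) < 3 * np.sqrt(0.95 * 0.05 / n_rep)


class TestGroupCompare:
    def _frames(self, mu_case=0.0, n=50, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"S{i}" for i in range(2 * n)]
        features = pd.DataFrame(
            {
                "metric": np.concatenate(
                    [rng.normal(mu_case, 1, n), rng.normal(0, 1, n)]
                ),
                "sex": ["female", "male"] * n,
            },
            index=idx,
        )
        records = pd.DataFrame(
            {"group": ["PMS"] * n + ["RRMS-Stable"] * n}, index=idx
        )
        return features, records

    def test_separated_means_tiny_p(self):
        features, records = self._frames(mu_case=5.0)
        out = group_compare(features, records)
        assert out.loc["metric", "p"] < 1e-10
        assert out.loc["metric", "case_mean"] == pytest.approx(5.0, abs=0.5)

    def test_categorical_uses_chi2(self):
        features, records = self._frames()
        out = group_compare(features, records)
        assert out.loc["sex", "test"] == "chi2"

    def test_constant_metric_rejected(self):
        features, records = self._frames()
        features["metric"] = 1.0
        with pytest.raises(ValueError):
            group_compare(features, records)

    def test_tiny_groups_rejected(self):
        features, records = self._frames(n=1)
        with pytest.raises(ValueError):
            group_compare(features, records)


class TestAssociateMetrics:
    def test_two_contrasts_and_bh_column(self):
        rng = np.random.default_rng(3)
        n = 60
        idx = [f"S{i}" for i in range(3 * n)]
        records = pd.DataFrame(
            {
                "group": ["RRMS-Stable"] * n + ["RRMS-Suspected"] * n + ["PMS"] * n,
                "age": rng.normal(55, 8, 3 * n),
                "sex": rng.choice(["female", "male"], 3 * n),
                "bmi": rng.normal(28, 5, 3 * n),
            },
            index=idx,
        )
        shift = np.concatenate([np.zeros(2 * n), np.full(n, 1.5)])
        features = pd.DataFrame(
            {"TAC": rng.normal(0, 1, 3 * n) + shift, "flat": rng.normal(0, 1, 3 * n)},
            index=idx,
        )
        out = associate_metrics(features, records)
        assert set(out["contrast"]) == {"PMS_vs_RRMS", "Suspected_vs_Stable"}
        row = out[(out.contrast == "PMS_vs_RRMS") & (out.predictor == "TAC")].iloc[0]
        assert row.estimate > 0 and row.p < 0.01
        assert "SD" in row.scaling_note  # TAC enters scaled by its SD
        assert out["p_bh"].notna().all()


class TestM10Sensitivity:
    def test_activity_inside_m10_equals_daily_tac(self, cutpoints):
        from actirhythm.core import CleanSeries
        import datetime as dt
        from conftest import make_day

        counts = np.zeros(MINUTES_PER_DAY)
        counts[10 * 60 : 18 * 60] = 1000.0  # 8 h of activity, inside any M10
        days = []
        for i in range(3):
            d = make_day(counts, date=dt.date(2022, 5, 2 + i), mark=False)
            d.wear = np.ones(MINUTES_PER_DAY, dtype=bool)  # worn all night
            d.valid = True
            days.append(d)
        clean = CleanSeries("S1", days)
        full = aggregate_pa(clean, cutpoints)
        windowed = m10_sensitivity([clean], cutpoints)
        assert windowed.loc["S1", "M10_TAC"] == pytest.approx(full.tac)

    def test_uniform_profile_proportionality(self, cutpoints):
        counts = np.full(MINUTES_PER_DAY, 500.0)
        clean = make_clean([counts] * 3)
        full = aggregate_pa(clean, cutpoints)
        windowed = m10_sensitivity([clean], cutpoints)
        assert windowed.loc["S1", "M10_TAC"] == pytest.approx(full.tac * 600 / 1440)

    def test_windowed_contrast_keeps_sign(self, cutpoints):
        """A cohort contrast in full-day MVPA keeps its sign inside M10."""
        rng = np.random.default_rng(4)

        def subject(level, sid):
            days = []
            for _ in range(3):
                c = rng.lognormal(np.log(300), 1.0, MINUTES_PER_DAY)
                day_hours = slice(9 * 60, 21 * 60)
                hot = rng.random(720) < level
                seg = c[day_hours]
                seg[hot] = rng.lognormal(np.log(9000), 0.3, int(hot.sum()))
                c[day_hours] = seg
                days.append(np.round(c))
            return make_clean(days, subject_id=sid)

        high = [subject(0.20, f"H{i}") for i in range(5)]
        low = [subject(0.05, f"L{i}") for i in range(5)]
        full_diff = np.mean(
            [aggregate_pa(c, cutpoints).mvpa_min for c in high]
        ) - np.mean([aggregate_pa(c, cutpoints).mvpa_min for c in low])
        win = m10_sensitivity(high + low, cutpoints)
        win_diff = win.loc[[f"H{i}" for i in range(5)], "M10_MVPA"].mean() - win.loc[
            [f"L{i}" for i in range(5)], "M10_MVPA"
        ].mean()
        assert full_diff > 0 and win_diff > 0
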