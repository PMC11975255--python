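"""Single-component cosinor regression of activity on the 24-hour clock.

The model is ``x(t) = M + beta_c cos(omega t) + beta_s sin(omega t)`` with
``omega = 2*pi/period``; in the amplitude/acrophase parameterisation,
``x(t) = M + A cos(omega (t - phi))`` where ``A = sqrt(beta_c^2 + beta_s^2)``
and ``phi = atan2(beta_s, beta_c)/omega mod period``.  M is the MESOR
(rhythm-adjusted mean), A the amplitude, phi the acrophase (clock time of the
daily peak, hours).
"""

from __future__ import annotations

import numpy as np


class Cosinor:
    """Least-squares cosinor model for one subject's activity series.

    Parameters
    ----------
    values : array-like
        Activity values (typically minute counts pooled across valid days).
    hours : array-like
        Clock time of each value in hours (need not be sorted or unique
        across days; 14:30 on any day is 14.5).
    period : float
        Rhythm period in hours, default 24.
    """

    def __init__(self, values, hours, period: float = 24.0):
        values = np.asarray(values, dtype=float)
        hours = np.asarray(hours, dtype=float)
        keep = ~np.isnan(values)
        self.endog = values[keep]
        self.hours = hours[keep]
        self.period = float(period)
        if self.endog.size < 3 or np.unique(self.hours).size < 3:
            raise ValueError("cosinor fit needs >= 3 distinct clock times")

    def fit(self) -> "CosinorResults":
        omega = 2 * np.pi / self.period
        X = np.column_stack(
            [
                np.ones_like(self.hours),
                np.cos(omega * self.hours),
                np.sin(omega * self.hours),
            ]
        )
        beta, _, rank, _ = np.linalg.lstsq(X, self.endog, rcond=None)
        if rank < 3:
            raise ValueError("rank-deficient cosinor design (times do not vary)")
        resid = self.endog - X @ beta
        return CosinorResults(self, beta, resid)


class CosinorResults:
    def __init__(self, model: Cosinor, beta: np.ndarray, resid: np.ndarray):
        self.model = model
        self.params = beta
        self.resid = resid
        self.mesor = float(beta[0])
        self.amplitude = float(np.hypot(beta[1], beta[2]))
        scale = max(1.0, float(np.max(np.abs(model.endog))))
        if self.amplitude <= 1e-10 * scale:
            # a flat series has no phase (tiny amplitudes are lstsq noise)
            self.acrophase = float("nan")
        else:
            omega = 2 * np.pi / model.period
            self.acrophase = float(
                (np.arctan2(beta[2], beta[1]) / omega) % model.period
            )

    @property
    def rss(self) -> float:
        return float(np.sum(self.resid**2))

    def summary(self) -> str:
        lines = [
            "Cosinor regression (period = %.1f h)" % self.model.period,
            "n observations: %d" % self.model.endog.size,
            "MESOR:     %12.3f" % self.mesor,
            "Amplitude: %12.3f" % self.amplitude,
            "Acrophase: %12.3f h" % self.acrophase,
            "Residual SD: %10.3f" % float(np.std(self.resid)),
        ]
        return "\n".join(lines)


def cosinor_fit(values, hours, period: float = 24.0) -> tuple[float, float, float]:
    """Convenience wrapper returning (mesor, amplitude, acrophase)."""
    res = Cosinor(values, hours, period=period).fit()
    return res.mesor, res.amplitude, res.acrophase


def circular_mean_hours(hours: np.ndarray, period: float = 24.0) -> float:
    """Circular mean of clock times in hours on a ``period``-hour dial."""
    hours = np.asarray(hours, dtype=float)
    hours = hours[~np.isnan(hours)]
    ang = 2 * np.pi * hours / period
    mean = (
        np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang))) * period / (2 * np.pi)
    ) % period
    return float(mean if mean < period else 0.0)  # guard the 0/period wrap
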