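"""Synthetic actigraphy cohorts with known generating structure.

The generator emulates the data the analysis assumes: a three-group MS cohort
(RRMS-Stable, RRMS-Suspected progression, PMS), each subject wearing the
device 24 h/day for ~14 days, recorded as minute-epoch vector-magnitude
counts.  Two generating layers are coupled:

* a two-state (sedentary/active) Markov chain over minutes, whose
  sedentary->active probability is modulated over the day so that the
  equilibrium probability of being active follows a cosinor curve
  (MESOR/amplitude/acrophase); the active->sedentary probability is held
  constant, so the chain's ASTP is the generating parameter exactly;
* count magnitudes: active minutes draw lognormal counts (heavy right tail,
  as real count data), sedentary minutes draw small counts with occasional
  zeros, and minutes inside the sleep window draw near-zero counts whatever
  the latent state.

Nonwear episodes (all-zero runs of >= 90 min) and daylight-saving transitions
can be injected.  Self-reported activity (IPAQ) is derived from each
subject's true MVPA/LIPA minutes plus reporting noise, so calibration against
self-report is testable.  Every per-subject generating parameter is retained
in ``SyntheticCohort.truth`` for recovery tests.

Group default parameters carry the three groups' published mean cosinor and
fragmentation values (MESOR/amplitude in counts, acrophase in hours, ASTP as
the active->sedentary probability), with covariate distributions matching the
cohort's demographics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MINUTES_PER_DAY,
    CutPoints,
    DayRecord,
    MinuteSeries,
    SubjectRecord,
)

__all__ = [
    "GroupParams",
    "CohortConfig",
    "SyntheticCohort",
    "default_group_params",
    "simulate_cosinor_series",
    "simulate_markov_states",
    "simulate_subject",
    "simulate_cohort",
    "inject_dst",
    "write_counts_csv",
    "write_covariates_csv",
    "write_truth_json",
]

_OMEGA = 2 * np.pi / 24.0  # radians per hour for a 24-h rhythm

#: MET weights used to turn true intensity minutes into an IPAQ-like
#: MET-minute/week summary (moderate-vigorous ~4 METs, light ~2.5).
_MET_MVPA = 4.0
_MET_LIPA = 2.5

#: Standard IPAQ categorical thresholds, MET-min/week.
_IPAQ_MODERATE = 600.0
_IPAQ_HIGH = 3000.0


@dataclass(frozen=True)
class GroupParams:
    """Generating parameters for one cohort group."""

    name: str = "group"
    mesor: float = 1200.0           # counts; rhythm-adjusted mean of the activity curve
    amplitude: float = 2000.0       # counts; half peak-to-trough of the curve
    acrophase: float = 14.5         # hours in [0, 24); time of the daily peak
    noise_sd: float = 500.0         # counts; additive noise of the pure-signal generator
    p_active_given_sedentary: float = 0.09   # SATP-like baseline transition prob
    p_sedentary_given_active: float = 0.27   # ASTP-like transition prob (held constant)
    active_count_log_mean: float = float(np.log(5200.0))
    active_count_log_sd: float = 0.35
    sedentary_count_log_mean: float = float(np.log(150.0))
    sedentary_count_log_sd: float = 1.0
    p_zero_sedentary: float = 0.30  # chance a waking sedentary minute records 0
    sleep_window: tuple[float, float] = (23.0, 7.0)  # clock hours, wraps midnight
    p_zero_sleep: float = 0.50
    sleep_count_log_mean: float = float(np.log(120.0))
    sleep_count_log_sd: float = 1.0
    day_effect_sd: float = 0.25     # SD of the per-day lognormal activity multiplier
    hour_effect_sd: float = 0.60    # SD of the per-hour lognormal activity multiplier
    nonwear_rate: float = 0.15      # expected nonwear episodes per day
    nonwear_min_len: int = 120      # minutes; must be >= 90 to be detectable
    age_mean: float = 54.0
    age_sd: float = 8.0
    bmi_mean: float = 28.5
    bmi_sd: float = 6.0
    p_female: float = 0.70
    ipaq_noise_sd: float = 400.0    # MET-min/week reporting noise

    def validate(self) -> None:
        for p in (
            self.p_active_given_sedentary,
            self.p_sedentary_given_active,
            self.p_female,
        ):
            if not (0 < p < 1):
                raise ValueError(f"probabilities must lie in (0,1), got {p}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if not (0 <= self.acrophase < 24):
            raise ValueError("acrophase must lie in [0, 24)")
        if self.nonwear_min_len < 90:
            raise ValueError(
                "nonwear_min_len < 90 would be undetectable by the 90-minute "
                "zero-run rule"
            )


def default_group_params() -> dict[str, GroupParams]:
    """Per-group defaults reflecting the study groups' published means.

    Cosinor parameters (MESOR, amplitude, acrophase) and the Markov
    transition probabilities (SATP/ASTP) carry each group's reported mean;
    covariate distributions match the cohort table.  Count-magnitude
    parameters are chosen so cohort-level TAC and MVPA land on the reported
    scales (TAC ~2e6 counts/day, MVPA ~40-60 min/day).
    """
    base = GroupParams()
    return {
        "RRMS-Stable": replace(
            base,
            name="RRMS-Stable",
            mesor=1313.0,
            amplitude=2290.0,
            acrophase=14.56,
            p_active_given_sedentary=0.09,
            p_sedentary_given_active=0.27,
            active_count_log_mean=float(np.log(5200.0)),
            age_mean=53.0,
            age_sd=7.0,
            bmi_mean=29.4,
            bmi_sd=6.4,
            p_female=0.71,
        ),
        "RRMS-Suspected": replace(
            base,
            name="RRMS-Suspected",
            mesor=1264.0,
            amplitude=2218.0,
            acrophase=14.61,
            p_active_given_sedentary=0.09,
            p_sedentary_given_active=0.26,
            active_count_log_mean=float(np.log(5400.0)),
            age_mean=54.0,
            age_sd=8.0,
            bmi_mean=28.2,
            bmi_sd=5.6,
            p_female=0.74,
        ),
        "PMS": replace(
            base,
            name="PMS",
            mesor=1120.0,
            amplitude=1923.0,
            acrophase=14.76,
            p_active_given_sedentary=0.09,
            p_sedentary_given_active=0.30,
            active_count_log_mean=float(np.log(4900.0)),
            age_mean=57.0,
            age_sd=9.0,
            bmi_mean=28.0,
            bmi_sd=6.2,
            p_female=0.67,
        ),
    }


@dataclass
class CohortConfig:
    n_per_group: int = 85
    n_days: int = 14
    epoch_seconds: int = 60
    group_params: dict[str, GroupParams] = field(default_factory=default_group_params)
    dst_events: list[tuple[int, str]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.epoch_seconds != 60:
            raise ValueError("only 60-second epochs are supported")
        for gp in self.group_params.values():
            gp.validate()
        for day, direction in self.dst_events:
            if not (0 <= day < self.n_days):
                raise ValueError(f"dst event day {day} outside 0..{self.n_days - 1}")
            if direction not in ("forward", "back"):
                raise ValueError(f"dst direction must be forward|back, got {direction}")


@dataclass
class SyntheticCohort:
    series: list[MinuteSeries]
    records: list[SubjectRecord]
    truth: dict[str, dict]
    config: CohortConfig


# ---------------------------------------------------------------------------
# Generators


def simulate_cosinor_series(
    mesor: float,
    amplitude: float,
    acrophase: float,
    noise_sd: float,
    n_days: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Pure cosinor signal sampled per minute with additive Gaussian noise.

    Returns an (n_days, 1440) array of
    ``mesor + amplitude * cos(omega * (t - acrophase)) + noise``.  The output
    is a detrended activity signal and may go negative when the amplitude
    exceeds the MESOR (as the least-squares cosinor of skewed count data
    routinely does); it is not truncated, so estimator-recovery studies see
    the generating parameters without truncation bias.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_days * MINUTES_PER_DAY) / 60.0  # hours
    x = mesor + amplitude * np.cos(_OMEGA * (t - acrophase))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    return x.reshape(n_days, MINUTES_PER_DAY)


def simulate_markov_states(
    p_sa: np.ndarray | float,
    p_as: float,
    n_minutes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary active(1)/sedentary(0) minute chain.

    ``p_sa`` may be a scalar or a per-minute vector (time-varying
    sedentary->active probability); ``p_as`` is constant so the chain's
    active->sedentary transition probability equals it exactly.
    """
    p_sa = np.broadcast_to(np.asarray(p_sa, dtype=float), (n_minutes,))
    u = rng.random(n_minutes)
    states = np.empty(n_minutes, dtype=np.int8)
    # start from the equilibrium of the first minute's probabilities
    pi0 = p_sa[0] / (p_sa[0] + p_as)
    s = 1 if u[0] < pi0 else 0
    states[0] = s
    for t in range(1, n_minutes):
        if s == 1:
            s = 0 if u[t] < p_as else 1
        else:
            s = 1 if u[t] < p_sa[t] else 0
        states[t] = s
    return states


def _activity_probability_curve(params: GroupParams, n_days: int) -> np.ndarray:
    """Per-minute target probability of being active.

    The cosinor curve (MESOR/amplitude/acrophase) is mapped onto the Markov
    equilibrium: the baseline equilibrium pi0 = p_sa/(p_sa+p_as) is modulated
    multiplicatively by the relative cosinor (1 + (A/M) cos(...)), clipped to
    (0.005, 0.95).  This couples the rhythm and fragmentation layers: a
    stronger amplitude concentrates active minutes around the acrophase.
    """
    t = np.arange(n_days * MINUTES_PER_DAY) / 60.0
    rel = 1.0 + (params.amplitude / max(params.mesor, 1e-9)) * np.cos(
        _OMEGA * (t - params.acrophase)
    )
    pi0 = params.p_active_given_sedentary / (
        params.p_active_given_sedentary + params.p_sedentary_given_active
    )
    return np.clip(pi0 * rel, 0.005, 0.95)


def _sleep_mask(params: GroupParams, n_days: int) -> np.ndarray:
    start, end = params.sleep_window
    hour = (np.arange(n_days * MINUTES_PER_DAY) % MINUTES_PER_DAY) / 60.0
    if start <= end:
        return (hour >= start) & (hour < end)
    return (hour >= start) | (hour < end)


def simulate_subject(
    params: GroupParams,
    n_days: int,
    seed: int | np.random.Generator,
    subject_id: str = "S000",
    start_date: str = "2022-05-02",
) -> tuple[MinuteSeries, dict]:
    """Simulate one subject's minute-epoch count series plus generating truth.

    The latent chain yields the active/sedentary state per minute; counts are
    drawn per state (lognormal active, small sedentary, near-zero in the
    sleep window).  Nonwear episodes are inserted as all-zero runs of at
    least ``nonwear_min_len`` minutes with the truth wear flag set false.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_min = n_days * MINUTES_PER_DAY

    pi_t = _activity_probability_curve(params, n_days)
    if params.day_effect_sd > 0:
        # day-to-day variability in overall activity level, so interdaily
        # stability is below 1 as in real cohorts
        day_mult = rng.lognormal(0.0, params.day_effect_sd, size=n_days)
        pi_t = pi_t * np.repeat(day_mult, MINUTES_PER_DAY)
    if params.hour_effect_sd > 0:
        # hour-scale irregularity (errands, rest breaks): lowers interdaily
        # stability and raises intradaily variability toward realistic levels
        hour_mult = rng.lognormal(0.0, params.hour_effect_sd, size=n_days * 24)
        pi_t = pi_t * np.repeat(hour_mult, 60)
    pi_t = np.clip(pi_t, 0.005, 0.95)
    p_as = params.p_sedentary_given_active
    # sedentary->active rate that holds the equilibrium at pi_t
    p_sa_t = np.clip(pi_t * p_as / (1.0 - pi_t), 1e-4, 0.999)
    states = simulate_markov_states(p_sa_t, p_as, n_min, rng)

    counts = np.empty(n_min)
    active = states == 1
    counts[active] = rng.lognormal(
        params.active_count_log_mean, params.active_count_log_sd, size=int(active.sum())
    )
    n_sed = int((~active).sum())
    sed_counts = rng.lognormal(
        params.sedentary_count_log_mean, params.sedentary_count_log_sd, size=n_sed
    )
    sed_counts[rng.random(n_sed) < params.p_zero_sedentary] = 0.0
    counts[~active] = sed_counts

    sleep = _sleep_mask(params, n_days)
    n_sleep = int(sleep.sum())
    sleep_counts = rng.lognormal(
        params.sleep_count_log_mean, params.sleep_count_log_sd, size=n_sleep
    )
    sleep_counts[rng.random(n_sleep) < params.p_zero_sleep] = 0.0
    counts[sleep] = sleep_counts

    counts = np.round(counts)

    wear = np.ones(n_min, dtype=bool)
    n_episodes = rng.poisson(params.nonwear_rate * n_days)
    for _ in range(n_episodes):
        length = params.nonwear_min_len + int(rng.exponential(60.0))
        start = int(rng.integers(0, max(n_min - length, 1)))
        counts[start : start + length] = 0.0
        wear[start : start + length] = False

    dates = pd.date_range(start_date, periods=n_days, freq="D").date
    days = [
        DayRecord(
            date=dates[d],
            counts=counts[d * MINUTES_PER_DAY : (d + 1) * MINUTES_PER_DAY].copy(),
        )
        for d in range(n_days)
    ]
    series = MinuteSeries(subject_id, days)

    cp = CutPoints()
    worn = wear
    mvpa_per_day = float(np.sum((counts > cp.mvpa_min) & worn)) / n_days
    lipa_per_day = (
        float(np.sum((counts > cp.nonactive_max) & (counts <= cp.mvpa_min) & worn))
        / n_days
    )
    truth = {
        "params": asdict(params),
        "states": states,
        "wear": wear,
        "mvpa_min_per_day": mvpa_per_day,
        "lipa_min_per_day": lipa_per_day,
    }
    return series, truth


def inject_dst(
    series: MinuteSeries,
    day: int,
    direction: str,
    duplicate_values: np.ndarray | None = None,
) -> MinuteSeries:
    """Inject a daylight-saving transition into a simulated series.

    forward: the skipped hour (02:00-02:59 on the transition day) becomes
    missing.  back: the repeated hour (01:00-01:59) carries two observed
    values per minute — the second copy is stored as a duplicate block
    (``duplicate_values`` if given, else a copy of the observed hour) — and
    the final day loses its last hour (recording ends an hour early on wall
    clock), marked missing.
    """
    if not (0 <= day < series.n_days):
        raise IndexError(f"day {day} outside series of {series.n_days} days")
    if direction not in ("forward", "back"):
        raise ValueError("direction must be 'forward' or 'back'")
    out = series.copy()
    if direction == "forward":
        d = out.days[day]
        d.counts[120:180] = np.nan
        d.wear[120:180] = False
    else:
        d = out.days[day]
        second = (
            np.asarray(duplicate_values, dtype=float)
            if duplicate_values is not None
            else d.counts[60:120].copy()
        )
        if second.shape != (60,):
            raise ValueError("duplicate block must hold 60 minute values")
        d.duplicate = (60, second)
        last = out.days[-1]
        last.counts[1380:1440] = np.nan
        last.wear[1380:1440] = False
    return out


def _ipaq_category(met_min: float) -> str:
    if met_min >= _IPAQ_HIGH:
        return "high"
    if met_min >= _IPAQ_MODERATE:
        return "moderate"
    return "low"


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate the full three-group cohort; deterministic given config.seed."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    series_list: list[MinuteSeries] = []
    records: list[SubjectRecord] = []
    truth: dict[str, dict] = {}
    group_seeds = root.spawn(len(config.group_params))
    sid = 0
    for (gname, gp), gseed in zip(config.group_params.items(), group_seeds):
        subj_seeds = gseed.spawn(config.n_per_group)
        for j, sseed in enumerate(subj_seeds):
            rng = np.random.default_rng(sseed)
            subject_id = f"S{sid:04d}"
            sid += 1
            series, t = simulate_subject(
                gp, config.n_days, rng, subject_id=subject_id
            )
            for day, direction in config.dst_events:
                series = inject_dst(series, day, direction)
            age = float(np.clip(rng.normal(gp.age_mean, gp.age_sd), 40, 90))
            bmi = float(np.clip(rng.normal(gp.bmi_mean, gp.bmi_sd), 16, 55))
            sex = "female" if rng.random() < gp.p_female else "male"
            met = (
                7.0
                * (
                    _MET_MVPA * t["mvpa_min_per_day"]
                    + _MET_LIPA * t["lipa_min_per_day"]
                )
                + rng.normal(0.0, gp.ipaq_noise_sd)
            )
            met = float(max(met, 0.0))
            records.append(
                SubjectRecord(
                    subject_id=subject_id,
                    group=gname,
                    age=age,
                    sex=sex,
                    bmi=bmi,
                    ipaq_met_min=met,
                    ipaq_category=_ipaq_category(met),
                )
            )
            truth[subject_id] = {**t, "group": gname}
            series_list.append(series)
    return SyntheticCohort(series_list, records, truth, config)


# ---------------------------------------------------------------------------
# Writers


def write_counts_csv(series_list: list[MinuteSeries], path: str | Path) -> None:
    """Minute-level CSV: subject_id, date, minute_of_day, count, wear.

    Missing minutes are written with an empty count field (never zero:
    zero means "no movement").  The wear column reflects current flags.
    """
    frames = []
    for series in series_list:
        for day in series.days:
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": series.subject_id,
                        "date": str(day.date),
                        "minute_of_day": np.arange(MINUTES_PER_DAY),
                        "count": day.counts,
                        "wear": day.wear.astype(int),
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_covariates_csv(records: list[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.age,
                "sex": r.sex,
                "bmi": r.bmi,
                "ipaq_met_min": r.ipaq_met_min,
                "ipaq_category": r.ipaq_category,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_truth_json(cohort: SyntheticCohort, path: str | Path) -> None:
    """JSON sidecar with per-subject generating parameters (arrays summarized)."""
    payload = {}
    for sid, t in cohort.truth.items():
        payload[sid] = {
            "group": t["group"],
            "params": t["params"],
            "mvpa_min_per_day": t["mvpa_min_per_day"],
            "lipa_min_per_day": t["lipa_min_per_day"],
            "n_active_minutes": int(np.sum(t["states"])),
            "n_nonwear_minutes": int(np.sum(~t["wear"])),
        }
    Path(path).write_text(json.dumps(payload, indent=2))
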