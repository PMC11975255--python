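# Methods

This note documents the models and procedures implemented in `actirhythm`,
the assumptions behind them, the parameters that matter, and the design
choices made where the methodology was genuinely open.

## Data model and preprocessing

The substrate is the minute-epoch vector-magnitude activity count: each
subject contributes calendar days of exactly 1440 minute slots (midnight to
23:59). Three states are distinguished and never conflated: a **zero count**
(no movement), a **missing** minute (no observation, e.g. the hour skipped
by a spring-forward clock change; stored as NaN, never as 0), and
**nonwear** (device off the wrist, inferred).

* **Nonwear** — every maximal run of ≥ 90 consecutive zero-count minutes is
  flagged nonwear. Runs are detected on the subject's concatenated series
  and mapped back to days, so an episode straddling midnight is caught; the
  per-day variant is also exposed. Missing minutes break zero runs (a gap is
  not evidence of zeros) and are themselves not wear.
* **Valid day** — ≥ 1296 wear minutes (90% of the day).
* **Daylight saving** — a spring-forward transition leaves one hour missing;
  it is imputed minute-wise from the mean of the same minute-of-day over the
  subject's *other valid days*. A fall-back transition yields a duplicated
  hour (stored as an explicit duplicate block), resolved to the minute-wise
  mean of its two copies; the resulting short final hour of the last day is
  imputed as above. Imputed minutes count as wear — imputation exists
  precisely to restore complete days. Whether a study's wear-time
  denominator includes imputed minutes is generally unstated in the field;
  this package includes them, and revalidates days after imputation.
* **Inclusion** — subjects need ≥ 3 valid days; exclusions are logged with a
  reason ("never returned" / "insufficient valid days").

Preprocessing is idempotent: all flags are deterministic functions of the
counts, so reprocessing the surviving days reproduces the same result.

## Intensity classification and calibration

Minutes are classed nonactive (count ≤ `nonactive_max`), LIPA, or MVPA
(count > `mvpa_min`); the reference thresholds are 2000 and 6750 counts,
the pipeline's defaults. Optional calibration searches the grid
`nonactive_max ∈ {500..4000 step 250}`, `mvpa_min ∈ {4000..10000 step 250}`
(a span covering published wrist cut points) for the pair maximizing
concordance between accelerometry-derived and self-reported activity. The
concordance statistic is the mean of (a) the Spearman correlation between
MVPA min/day and IPAQ MET-min/week and (b) the linear-weighted kappa
between tertiles of the two — chosen because it exercises both the
continuous and the ordinal face of IPAQ; exact calibration criteria used in
cohort studies are typically unpublished, so this statistic is a documented
choice, not a reproduction. Ties are broken toward the pair closest
(Euclidean) to the reference (2000, 6750). Constant IPAQ is rejected:
concordance is undefined.

## Physical-activity metrics

Per valid day, over wear minutes: TAC = Σ counts; TLAC = Σ log(1 + count)
(the log1p transform is the standard epoch-count choice and handles zeros);
intensity minutes per the cut points; TAC in twelve 2-hour bins.
Fragmentation dichotomizes minutes at the nonactive cut — one consistent
dichotomy for SATP and ASTP — and counts transitions only between
consecutive wear minutes: a nonwear gap breaks a bout without fabricating a
transition, and the day's final bout contributes minutes but no transition
(censoring rather than inventing a midnight transition). Consequently ASTP
equals the reciprocal mean active-bout length on days ending sedentary, a
property the tests verify by exhaustive enumeration.

Subject-level features average each daily metric over valid days; the
composition ratios are formed from the averaged minutes (average-then-ratio,
documented since ratio-then-average differs for short days); days with
undefined fragmentation drop out of that average only.

## Circadian metrics

* **M10 / L5** — means over 600- and 300-minute windows of the subject's
  mean diurnal profile (minute-of-day mean over valid days, nonwear treated
  as missing; minutes unobserved on all days filled by circular linear
  interpolation). Windows are circular, since the least-active 5 hours
  commonly wrap midnight; ties break toward the earliest start. Midpoints
  are the window centers as clock time. RA = (M10 − L5)/(M10 + L5).
  Landmarks are computed on the raw count scale by default — reported group
  magnitudes in wrist-count cohorts (M10 ≈ 2100–2500) are count-scale even
  where the label says "log acceleration" — with a `log_scale` flag for the
  log1p alternative.
* **DARE** — in-window share of 24-h activity; the daytime window defaults
  to 08:00–20:00 and is configurable, because the daytime definition is not
  standardized and the value is window-dependent.
* **Cosinor** — least squares on x(t) = M + β_c·cos(ωt) + β_s·sin(ωt),
  ω = 2π/24 h, fitted to minute-level data pooled across valid days (the
  standard single-subject practice; fitting the averaged profile instead is
  available upstream by construction). Amplitude = √(β_c² + β_s²);
  acrophase = atan2(β_s, β_c)/ω mod 24. Amplitudes below 1e-10 of the data
  scale report a missing acrophase (a flat series has no phase). Designs
  with fewer than 3 distinct clock times are rejected.
* **IV / IS** — computed on hourly means (the conventional bin width; the
  reported magnitudes in wrist cohorts are consistent with hourly bins).
  With N observed hours x_i, hour-of-day means x̄_h (p = 24), grand mean x̄:
  IV = N·Σ(x_i − x_{i−1})²/((N−1)·Σ(x_i − x̄)²),
  IS = N·Σ_h(x̄_h − x̄)²/(p·Σ(x_i − x̄)²). Pairs with a missing member drop
  from the numerator of IV; zero-variance series are rejected as undefined.

## Functional PCA

Profiles are binned to 10-minute resolution (144 points) before
decomposition — at cohort sizes of a few hundred this stabilizes the
covariance without distorting landmark timing; no smoothing is applied by
default. The centered profile matrix is SVD-decomposed (equivalently, the
sample covariance across subjects is eigen-decomposed); K = 5 components
are retained as CR features, since in wrist-accelerometry cohorts the first
four or five components capture the interpretable diurnal variability.
Eigenfunction signs are conventional; they are fixed deterministically
(positive integral, falling back to a positive maximum-magnitude entry when
the integral is near zero), with scores flipped consistently, so component
directions are reproducible across runs and platforms.

## JIVE

Each feature block (PA and CR, features × subjects over identical subject
order) is prepared by per-feature z-scoring (ddof = 1) followed by division
by the block Frobenius norm, so blocks with unequal feature counts
contribute equal total variation — the standard JIVE convention where the
block-scaling choice is otherwise unreported. Estimation alternates: the
joint structure is the rank-r_J truncated SVD of the stacked
individual-removed blocks; each individual structure is the rank-r_k
truncated SVD of the block's joint-removed residual projected orthogonally
to the joint row space; iterated until the total squared residual changes
by < 1e-8 (max 500 iterations; nonconvergence raises with diagnostics), and
orthogonality of individual to joint is enforced exactly at the end. The
additive identity X_k = J_k + A_k + E_k holds by construction; the energy
split ‖X‖² = ‖J‖² + ‖A‖² + ‖E‖² holds within the convergence tolerance
(the J-vs-E cross-term vanishes exactly only summed across blocks).

Default ranks are (joint 1, PA 4, CR 3) — the component-count shape used in
the motivating analysis — with a permutation selector available: the joint
rank grows while observed singular values of the stacked blocks exceed the
(1 − α) quantile of nulls obtained by permuting subject order within one
block (destroying cross-block alignment while preserving within-block
structure); individual ranks are tested the same way against nulls that
permute entries within feature rows of the joint-removed residual. At least
20 permutations are required; α defaults to 0.05.

Exported scores are standardized to unit variance and sign-oriented by the
same rule as the fPCA components applied to their loading vectors. The
loading report lists, per component, features whose squared loading exceeds
a threshold (default 5%) of the component's total squared loading; loading
vectors are unit-norm, so the reported relative magnitude is the squared
loading itself.

The acrophase enters the CR block in raw hours. An (sin, cos) encoding
avoiding the 0/24 discontinuity was considered; in cohorts whose acrophases
concentrate mid-afternoon the discontinuity is never approached, and raw
hours keep the loading report interpretable. This is the one place the
implementation prefers interpretability over circular correctness; users
analysing populations with night-shifted phases should add the encoded
columns themselves.

## Association models

Group descriptives use Welch's t test for continuous metrics (the robust
default where only "t tests" is conventionally stated; the pooled-variance
version is a flag away) and Pearson's χ² for categorical ones. Per-metric
logistic regressions model a binary group contrast on one metric plus age,
sex and BMI, with Wald 95% CIs (profile-likelihood intervals differ
negligibly at n ≈ 250 and Wald matches the common reporting convention);
TAC and TLAC are divided by their sample SD before entry — their raw scales
(10⁶, 10³) would otherwise produce unreadable coefficients — and the
scaling is recorded in the result. No multiple-testing correction is
applied to the primary p values, matching per-metric reporting practice; a
Benjamini–Hochberg column is emitted alongside. Perfect separation is
detected, flagged, and refitted with a small L2 penalty for a point
estimate only (CI and p withheld). Both contrasts — PMS vs combined RRMS,
and RRMS-Suspected vs RRMS-Stable — are emitted.

The M10 sensitivity analysis locates each subject's most-active 600-minute
circular window on their mean diurnal profile, recomputes the PA metrics
over wear minutes inside that window per valid day, and reruns the same
models — a guard against sleep-timing differences masquerading as activity
differences.

## Synthetic cohort generator

The generator produces what the analysis assumes: a three-group cohort
(RRMS-Stable, RRMS-Suspected, PMS) of minute-epoch counts. Two coupled
layers:

* a two-state sedentary/active Markov chain per minute, whose
  sedentary→active probability is modulated so the equilibrium
  P(active at t) follows the group's cosinor curve (clipped to
  (0.005, 0.95)); the active→sedentary probability is constant, so the
  chain's true ASTP equals the parameter exactly. This coupling makes
  fragmentation and rhythm interdependent — the premise of a joint PA/CR
  decomposition. Per-day and per-hour lognormal multipliers (SD 0.25 and
  0.6) add the day-to-day and hour-scale irregularity real cohorts show.
* count magnitudes drawn by state: lognormal for active minutes (heavy
  right tail, as count data; group log-means chosen so cohort TAC lands at
  the 2×10⁶/day scale and MVPA at 40–100 min/day), small counts with 30%
  zeros for waking sedentary minutes, and near-zero draws inside the sleep
  window (23:00–07:00). The sleep window affects counts only, never the
  latent chain — forcing the state would add a spurious transition per
  night and bias ASTP.

Group defaults carry the published group means for the cosinor parameters
(MESOR 1313/1264/1120 counts, amplitude 2290/2218/1923, acrophase
14.56/14.61/14.76 h), the transition probabilities (ASTP 0.27/0.26/0.30,
SATP 0.09) and covariate distributions (age, BMI, sex mix). Nonwear
episodes arrive at 0.15/day with length ≥ 120 min (episodes shorter than
90 min are rejected at validation — they would be undetectable by the
nonwear rule). IPAQ MET-min/week = 7·(4·MVPA + 2.5·LIPA) min/day plus
Gaussian reporting noise (SD 400), floored at zero, with the standard
600/3000 category thresholds. Daylight-saving events can be injected
(forward: the 02:00 hour goes missing; back: the 01:00 hour is duplicated
and the final day ends an hour short). Everything is driven by
`numpy.random.SeedSequence` spawning, so a cohort is bit-reproducible from
its seed, and all generating truth (states, wear, parameters) is retained.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: device-level noise and the 30 Hz→count
conversion; realistic sleep architecture (the sleep window is fixed, not
subject-specific); within-group heterogeneity of rhythm parameters beyond
the day/hour multipliers. Its interdaily stability (≈ 0.7) runs above
wrist-cohort values (≈ 0.26) and its relative amplitude (≈ 0.93) above
(≈ 0.87–0.91): simulated days are more alike, and simulated nights quieter,
than real ones. Group *contrasts* in TAC, MVPA, ASTP and cosinor amplitude
carry the intended signs and are what the qualitative tests assert;
absolute IV/IS/RA/DARE levels are not calibrated to any cohort.

A separate pure-signal generator produces cosinor + Gaussian noise minute
series without truncation at zero (the trough of a count-scale cosinor with
amplitude > MESOR is negative; truncation would bias estimator-recovery
studies). It underlies the recovery harnesses.

## Recovery harnesses and problem sizes

`actirhythm.recovery` simulates cohorts from known parameters and reports
cross-subject mean estimates with Monte-Carlo standard errors. The standard
configurations — 85 subjects × 14 days for cosinor recovery (noise SD 500
counts) and for ASTP recovery (binary chains at 0.30/0.09) — mirror a
single study group's size and wear protocol. Unit and property tests use
smaller cohorts (tens of subjects, 3–7 days) where the asserted bands are
comfortably wider than the Monte-Carlo error at that size; the JIVE
structural suite and the type-I-error calibration run at n = 250 subjects
(500 null replicates), the full-cohort scale.

## Known limitations

* The cosinor is single-component; multi-harmonic extensions are out of
  scope.
* Fragmentation stops at SATP/ASTP; bout-distribution and Gini-type indices
  are not implemented.
* Sleep detection and sleep parameters are out of scope; the M10-window
  sensitivity analysis is the provided guard against sleep-timing
  confounding.
* JIVE is two-block, dense, non-robust; no sparse or >2-block variants.
* The calibration statistic is a documented stand-in for whatever criterion
  a given study used; with noiseless self-report it recovers the generating
  classification (tested), but its behaviour under realistic IPAQ noise is
  cohort-dependent.
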