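# Methods

`acticomplex` quantifies two dynamical properties of epoch-level
accelerometer magnitude traces beyond their mean and variance: how
strongly the signal repeats itself (correlation dimension) and how
fragmented the rest/activity pattern is (state-transition indices kAR
and kRA). This note documents the models, the estimators, the
numerical choices, and what the synthetic-data generator does and does
not emulate.

## Signal model and preprocessing

The input is a magnitude series in gravitational units g, one value per
fixed epoch (typically 5 s), recorded continuously over several days,
day and night. The pipeline coarse-grains to the analysis timescale by
averaging non-overlapping blocks (default: blocks of 12, i.e. 1-minute
epochs), dropping a trailing partial block. Gaps are rejected rather
than imputed: every estimator below assumes even spacing.

Traditional measures on the analysis-scale series: mean, sample SD
(n−1 denominator), coefficient of variation CoV = sd/mean, and the
lag-1 autocorrelation computed as the lag-1 autocovariance over the
variance, both centred on the global mean. A constant series has
undefined AC1 and a zero-mean series an undefined CoV; both are
reported as NaN with a flag, never raised mid-cohort.

## Correlation dimension

The series is delay-embedded, `X_i = (x_i, x_{i+τ}, …, x_{i+(d−1)τ})`,
and the correlation integral

    C_d(r) = 2 / (N(N−1)) · #{(i,j), i<j : |X_i − X_j| ≤ r}

is evaluated on a grid of radii (N = n − (d−1)τ vectors; self-matches
excluded; a pair at distance exactly r counts as a neighbor — a
measure-zero convention fixed so exact oracle tests are well defined).
For small r, `C_d(r) ~ r^ν`; ν is estimated as the OLS slope of
log C on log r over all grid radii with C > 0. Radii with zero counts
carry no information at that scale and are dropped; at least three
positive radii are required. No automatic scaling-region detection is
attempted — the fit range is part of the configuration, and the R² of
the fit is reported so poorly linear curves are visible.

Defaults: d = 6, τ = 1, Euclidean metric, 20 log-spaced radii spanning
0.03–0.3 in units of the series' own sample SD (so different subjects
are probed at comparable relative tolerances; the conventional radius
0.2 lies inside the range). Absolute radii are recorded in every
output. For stochastic signals ν is *not* an intrinsic fractal
dimension — it depends on d, the radius range, the metric and the
timescale — so only comparisons at identical settings are meaningful.
The sensitivity sweep (`sweep` subcommand) re-runs the extraction over
a parameter grid and reports Spearman rank correlations of each
measure against the default cell to check that orderings, not absolute
values, are what the analysis rests on.

Pair counting is exact (no approximate neighbor search: group
differences of interest are small). The kernel is a blocked O(N²)
loop compiled with numba, accumulating each squared distance in index
order and comparing `sqrt` to r, which makes its counts bit-identical
to a naive double loop; tests additionally cross-check against
`scipy.spatial.cKDTree.count_neighbors`. A 14-day, 1-minute trace
(N ≈ 20 000, d = 6) takes roughly a second per subject on one core.

Sample entropy is provided as an auxiliary regularity measure:
`ln(C_d(r)/C_{d+1}(r))` with the Chebyshev metric, with templates of
both lengths counted over the same n − d starting positions (the
standard sample-entropy convention), which guarantees nonnegativity.
A constant series yields 0 by convention.

## Fragmentation

The analysis-scale trace is binarized at 0.0167 g (exactly-at-threshold
epochs count as rest; the conservative choice for noisy baselines).
Runs are maximal same-state stretches; the censored first and last runs
are included as complete runs, a negligible simplification over 7–14
day recordings. With N_t the number of runs of duration ≥ t, the
state-exit hazard is estimated at every represented duration
(N_t > N_{t+1}) as

    p(t) = (N_t − N_{t+g}) / (N_t · g),

where g is the interval to the next represented duration (g = 1 at the
largest t). A LOWESS fit (default fraction 0.5, one robustifying
iteration, fitted to the represented points only) locates the *constant
region*: the longest contiguous index window over which the smoothed
curve varies by at most one standard deviation of the raw p(t) curve
(population SD; ties go to the earlier window; with fewer than a
window of two, the flattest single point is used and flagged). The
index is the √N_t-weighted mean of p(t) over that region. kAR comes
from active runs, kRA from rest runs. Curves with fewer than three
represented durations use the whole curve as the region (flagged);
an index of exactly 1 (all runs ending immediately) is clamped to
1 − 1/(2N₁) so the downstream logit transform stays finite, and
flagged.

On a time-homogeneous two-state chain the run lengths are geometric and
p(t) is flat at the per-epoch hazard, so kAR/kRA recover the generating
hazards exactly in expectation — the basis of the parameter-recovery
tests. The LOWESS fraction interacts with curve length: 0.5 suits the
long hazard curves of multi-day recordings, while constructed short
plateau-recovery fixtures use 0.3 so the smoothing window resolves
their few-point edges.

## Statistical layer

One row per subject: group, age, sex, avg, sd, CoV, AC1, ν, kAR, kRA.
Pearson correlations between indicators use pairwise-complete rows.
Group comparisons use two-sided Mann–Whitney U tests: exact enumeration
of the permutation distribution of U (midranks for ties) when the
pooled sample size is ≤ 12, otherwise the tie-corrected normal
approximation without continuity correction (which tracks the exact p
more closely at moderate sizes).

Logistic regression of group membership (healthy = 1, patient = 0):
Model 1 uses age, sex, avg, CoV and AC1; Models 2–4 add ν, kAR and kRA
respectively. kAR/kRA are logit-transformed and z-scored, and rows with
|z| > 2 on a transformed fragmentation column are removed (logged per
subject). All continuous covariates are z-scored, so odds ratios are
per-SD — the paper-style "per 1 SD increase" reading; whether the
original analysis standardized the traditional covariates is not
stated, and standardizing everything is this package's documented
choice. Odds ratios carry Wald 95% CIs; AIC = 2k − 2lnL and
BIC = k·ln(n) − 2lnL with k including the intercept. Complete
separation, non-convergence, or fewer than 10 usable rows are reported
as structured warnings inside the model results rather than raised, so
a degenerate cohort still yields a complete report.

## Synthetic data

No generative model of real actigraphy is claimed; the generator is
built so that every downstream estimator has known ground truth.

* **Canonical signals.** Sine (default period 50π epochs — irrational,
  so integer sampling fills the cycle densely instead of revisiting a
  finite point set; its delay embedding is a closed curve with ν ≈ 1),
  Gaussian white noise (ν ≈ d for small d), stationary AR(1) red noise,
  and the Hénon map in its canonical chaotic regime (a = 1.4, b = 0.3,
  1000-iteration burn-in), whose x-orbit has a low, stable ν.

* **Rest/activity traces.** A two-state chain with per-epoch hazards
  p_AR (active→rest) and p_RA (rest→active). Constant within-state
  hazards make kAR/kRA exactly identifiable. Rest consolidation at
  night is a sinusoidal suppression of p_RA with its minimum at 03:00,
  scaled by `diurnal_depth`. Amplitudes are state-conditional:
  rest epochs uniform on [0, 0.01] g (strictly below the 0.0167 g
  cut-off), active epochs threshold + lognormal, multiplied by a
  log-additive AR(1) red-noise component (`ar1_phi`, `ar1_sd`). At the
  native epoch scale, binarization therefore recovers the latent state
  path exactly; after 1-minute averaging the states mix, which is the
  realistic regime the cohort-level tests run in.

* **Cohort templates.** Chosen for clinical plausibility of the two
  groups, then frozen. Healthy-like: activity bouts ~4 min
  (p_AR = 0.02/epoch at 5 s), daytime rest bouts ~3 min
  (p_RA = 0.025), strong nightly rest consolidation
  (diurnal_depth = 0.85), higher activity amplitudes, weak fast red
  noise (φ = 0.5, σ = 0.3). Patient-like: shorter activity bouts
  ~2 min (p_AR = 0.04), long low-activity periods ~20 min scattered
  through day *and* night (p_RA = 0.004, depth = 0.3), lower
  amplitudes, and a strong slow red-noise component (φ = 0.985 at 5 s,
  i.e. a correlation time of minutes surviving the 1-minute
  averaging). This reproduces the qualitative contrast the pipeline is
  meant to detect: consolidated, regular, high-amplitude healthy
  traces (low ν, low kAR, high kRA) versus fragmented, red-noise-like
  patient traces (high ν, high kAR, low kRA), with higher average
  activity in the healthy group. Both groups default to 14 simulated
  days; between-subject variation multiplies each subject's hazards,
  log-amplitude location and red-noise amplitude by lognormal jitter
  (default relative spread 0.15), with hazards clipped into (0, 1].
  Ages and sexes are drawn from group-specific marginals matching the
  cohorts the generator stands in for (healthy: 35.3 ± 10.3 y, 42%
  male; patient: 46.5 ± 12.0 y, 54% male).

What the generator does **not** emulate: raw tri-axial 100 Hz signals,
device noise and calibration error, nonwear, irregular sampling,
activity-intensity structure beyond a single lognormal, weekday/weekend
structure, or duration-dependent (non-geometric) bout hazards. Passing
tests therefore show that the estimators recover known structure of
this class and direction, not that real DM1 and control recordings
would separate with these effect sizes.

## Numerical and design choices

* Trailing partial blocks in coarse-graining are dropped, not averaged
  short (≤ 1 epoch of signal per subject).
* Radii are scaled by the sample SD (ddof = 1), consistent with the
  traditional-measures SD.
* Zero correlation sums are excluded from the log–log fit rather than
  treated as −∞.
* Exactly-at-threshold magnitudes binarize to rest.
* "Represented" durations are those with N_t > N_{t+1}; the weight at
  duration t is N_t, the number of runs contributing to that estimate.
* t_max is the longest observed run; no truncation.
* The constant-region criterion adds 1e-12 of numerical headroom so an
  exactly constant curve spans its whole domain despite LOWESS float
  jitter.
* Per-subject cohort seeds derive from the master seed via
  `numpy.random.SeedSequence`, so cohorts are reproducible element-wise
  and subjects are independent.
* Validation errors name the offending field; degenerate inputs inside
  a cohort run are flagged per subject and never abort the run (CLI
  exit code 2 signals partial success).

## Problem sizes used in the test suite

Oracle-equivalence checks run 50 random series up to n = 500 against a
naive double loop (bit-exact). Known-signal dimension checks use
n = 5000; the Hénon stability check compares n = 10 000 against
n = 50 000. Hazard recovery uses 200 000-epoch chains, hazards
0.02–0.5, 100 seeds each. The cohort-level check runs ten independent
20 + 20 cohorts of 14 simulated days at 1-minute analysis epochs and
requires the healthy-lower-ν, healthy-lower-kAR, healthy-higher-kRA
pattern at Mann–Whitney p < 0.01 in at least 9 of 10 cohorts. The
parameter-sweep ordering check (ν(sine) < ν(noise) over
d ∈ {4, 6, 8} × both metrics × two radius ranges, n = 20 000) skips
cells where the noise embedding has no neighbor pairs at the grid's
radii (small Euclidean radii at d ≥ 6 find none at feasible series
lengths); the ordering must hold in every computable cell.

## Known limitations

* No Theiler window: temporally adjacent embedded vectors count as
  neighbor pairs, which biases ν downward for strongly autocorrelated
  signals. All signals in a comparison share the bias direction.
* OLS over the whole radius range, not a detected scaling region; ν is
  a comparative index here, not a fractal-dimension estimate.
* The gap-corrected hazard estimator is a ratio estimator and is noisy
  at sparse tail durations; √N_t weighting and the constant region
  bound, but do not eliminate, tail influence.
* The exact Mann–Whitney branch enumerates all C(n1+n2, n1)
  assignments and is only used for pooled sizes ≤ 12.
* Logistic models with strongly separating predictors (easy to produce
  with the default synthetic templates) report separation warnings and
  their Wald CIs are then meaningless; this mirrors, rather than fixes,
  the small-sample behaviour of the modelling approach.
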