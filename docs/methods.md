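# Methods

This note documents the models behind `tagrecover`, the choices that were
genuinely open when it was designed, and what the synthetic cohorts used
in the tests do and do not establish about real tag records.

## Problem

A captured, instrumented and released animal behaves anomalously for some
hours: it moves differently (accelerometer metrics are suppressed or
elevated) and dives differently (for narwhal-like profiles, shallow dives
dominate immediately after release).  The quantity of interest is the
*return time* — the time after which a record reflects baseline
behaviour — estimated separately per behavioural stream, because a metric
like jerk can normalize hours before the dive profile does.  Animals can
be split into groups by covariates (the canonical example is handling
time, short < 58 min ≤ long) and the return times compared.

## Preprocessing

**Zero-offset depth correction.**  Pressure transducers drift with
temperature, so recorded surface depth wanders from zero.  The correction
is a two-stage moving-quantile smoother: a centred running median over
20 s (removes surface chop without eroding dives), then a centred running
0.01-quantile over 30 min of the first output (tracks the surface level;
the window accommodates dive cycles shorter than 30 min).  The corrected
trace is, by default, stage one minus stage two — the package also
offers raw minus stage two, which preserves within-dive high-frequency
content; both leave dive metrics (target depth relative to surface,
durations) essentially unchanged.  Windows are centred, shrinking
symmetrically at the record edges, so surface detection is not phase
shifted.  Constant offsets cancel exactly (shift equivariance), which the
tests verify.

**Dives.**  The surface zone is depth ≤ 20 m.  A dive is a maximal run of
samples strictly below the zone; its target depth is the deepest sample
and its duration the run length over the sampling rate.  Runs open at a
record boundary are discarded because their target depth is unknowable.
Depth categories are left-open/right-closed at the configured edges
(narwhal 160/360 m, bowhead 60/120 m — chosen to separate the species'
typical shallow / foraging / deep regimes).

**Acceleration metrics.**  The static (gravity/posture) component is a
4th-order Butterworth low-pass at 0.1 Hz applied forward–backward per
axis; zero-phase filtering avoids lag between the static estimate and the
raw series.  Dynamic acceleration is raw minus static; VeDBA is its
Euclidean norm, ODBA its L1 norm.  Jerk is the norm of the first
difference of raw acceleration multiplied by the sampling rate, so its
units are per second and values are comparable across sampling rates
(the derivative leaves the discretization convention open; scaling by fs
is this package's choice).  Metrics are aggregated to non-overlapping
block means, by default one minute, before model fitting — aggregation
damps serial correlation, and the minute scale keeps enough early-time
resolution to identify the decay slope.

## Quantile-regression recovery

At quantile level τ the model for a positive metric Y is

    log Y_τ(t) = β_ind + α_g · z,     z = 1/(t+1),

one offset per animal, one decay slope per group.  A categorical
covariate entering the slope is equivalent to one free slope per level,
which is how it is parameterized (the multiplicative
coefficient-times-covariate form is unidentified for a single categorical
factor).  The return time at tolerance δ solves exp(αz) = δ:
t_R = max(0, |α|/|ln δ| − 1), with |α| so that suppressed and elevated
responses are treated symmetrically.  δ defaults to 0.25 ("within 25% of
baseline").

**Fitting.**  The pinball objective Σ ρ_τ(log y − β − αz) separates over
groups (each animal belongs to one group), so groups are fitted
independently.  Two solvers:

* *exact* — the LP formulation solved with HiGHS; among exact minimizers
  (the pinball loss has flat optimal faces at small n) a secondary LP
  selects the solution with the smallest coefficient sum, which makes the
  fit deterministic and reduces to the lower endpoint of the optimal
  interval in the one-parameter case;
* *irls* — iteratively reweighted least squares with weights
  |τ − 1{r<0}| / max(|r|, 1e−6).  The normal equations of the
  animal-offsets-plus-slope design are diagonal-plus-border, so each
  iteration is a handful of segment sums over the observations;
  convergence tolerance 1e−8 on the parameters (1e−6 for warm-started
  bootstrap refits, which start at the full-sample solution).

The default picks the exact solver up to 2000 observations per group and
IRLS beyond; the smoothed solution agrees with the LP to well under the
parameter uncertainty at those sizes (tested), and the grid-search oracle
test pins the exact solver to the global optimum.

**Inference.**  Confidence intervals for t_R use a cluster bootstrap with
the animal as resampling unit (respecting within-animal serial
dependence), 1000 replicates by default, seeded.  With the typical
handful of animals per group, the plain percentile interval is
systematically too narrow — its width is driven by a spread estimated
from G clusters, which at G = 10 undercovers noticeably (measured ~70%
at nominal 95% on the default synthetic cohort).  The default interval is
therefore the *expanded percentile*: quantile levels widened by the
t-versus-normal ratio √(G/(G−1)) · t_{G−1,0.975}/z_{0.975}, the standard
small-sample correction for bootstrap intervals; the unadjusted
percentile band remains available.  Groups with fewer than three animals
fall back to a within-animal disjoint time-block bootstrap (blocks of
5 h) with a warning.  Slope contrasts (group vs group at fixed τ, or τ vs
τ within a group, the latter with paired resampling) are Wald tests with
the bootstrap standard error of the slope difference and a two-sided
normal p-value.

## Relative-entropy recovery

Hour t's dive profile is the probability vector P_t over (Shallow,
Medium, Deep), each dive weighted by its duration (count weighting is
available; duration weighting is the default because it measures time
budget rather than event frequency — an hour with one long deep dive is
a deep-diving hour).  Hours without dives carry no distribution and are
skipped, not imputed.  A finer joint category × duration-bin profile is
available for heatmap-style displays of how dive durations shift over
time, but inference always runs on the 3-category alphabet: with a few
dozen dives per hour, finer alphabets make the hourly distributions too
noisy to compare.

The baseline Q averages P_t over the normal region t > t_N (defaults:
narwhal 40 h, bowhead 10 h).  Tags drop off at staggered times, thinning
the animal sample, so a plain average would overweight the late, sparse
hours: the normal region is split at the drop points into half-open
segments (t_{i−1}, t_i], each segment's hourly distributions are
averaged, and segment means are combined with weights proportional to the
number of animals still active before each drop point.  Missing hours are
excluded from their segment mean with a renormalized divisor; an entirely
empty segment has its weight redistributed proportionally (warned).

Divergence is the Jensen–Shannon relative entropy in log base 2 —
symmetric, always finite, and exactly in [0, 1] (disjoint supports give
1).  The region of recovery (RoR) is the empirical 2.5–97.5% band, closed
at both endpoints, of the leave-one-out divergences J(P_t′ ‖ Q_{−t′}) for
normal-region hours t′ ≤ T, where T sits at one of the first drop points
so the animal set underlying P_t is stable.  Labels are +1 inside the
band, −1 outside.  For group comparisons the RoR pools the leave-one-out
divergences of the groups (assuming a shared baseline in the normal
region); per-group bands are also reported, and a large disparity between
them signals an individual-composition effect that confounds the group
contrast — the pipeline emits both so users can make that diagnosis.

## Breakpoint estimation

The cumulative sum of the ±1 labels falls at about −1/h while the animal
is perturbed and rises at about +1/h (minus the ~5% of baseline hours
outside the band) afterwards; the return time is the knot ψ of the
continuous piecewise-linear fit y = a + b₁x + b₂(x−ψ)₊.  ψ is found by
exhaustive search over interior observed hours with at least two points
on each side, OLS at each candidate, smallest SSR, ties to the smallest
ψ.  The grid search is exact at these series lengths and doubles as its
own oracle (an independently parameterized two-phase OLS cross-checks it
in the tests).  An exactly-linear series is flagged "no breakpoint".

**Uncertainty.**  Disjoint blocks of block_h hours (defaults 5 h narwhal,
2 h bowhead; the cube-root-of-series-length rule is available as a
helper) are drawn with replacement, as many as observed, and reassembled
*in their original temporal order* before recomputing the cumulative sum
and refitting.  Keeping blocks time-ordered is essential: placing
resampled blocks in random order destroys the fall-then-rise shape that
defines the estimand, and the breakpoint distribution becomes
uninformative (verified on the step-scenario tests, where random order
loses the changepoint in ~90% of replicates).  Order-preserving
resampling varies which stretches of the series contribute, exactly as a
cluster bootstrap varies which animals contribute.

A replicate counts as a detected recovery only if its fit has the
*recovery signature*: initial slope negative, post-knot slope positive.
Without this rule the estimator is degenerate under the null — a series
that is typical from the start has a noisily rising cumulative sum on
which a knot can always be placed, so spurious "recoveries" would be
reported.  Replicates without a signature are dropped and counted; if
they exceed half the replicates the result is "recovery not detected".
The reported return time is the mean replicate knot with the central 95%
of knots as interval.

## Synthetic cohorts

The accelerometer generator draws

    log y = β_i + (a_g + b_g ε) z + ε,      ε ~ N(0,1) i.i.d.,

so the τ-quantile is exactly linear in z with slope
α_g(τ) = a_g + b_g Φ⁻¹(τ): noise enters both level and slope, making the
tail and the median recover at genuinely different rates, which is the
phenomenon the quantile model exists to detect.  |b_g| ≤ 1 keeps the
conditional quantile function monotone on z ∈ (0,1].  Defaults: 10
animals per group, 100 h records, one observation per minute, β_i uniform
on (0.5, 1.5), slopes (−2.5, −1.0) for a long-handling group against
(−0.5, −1.0) for a short-handling one.

The dive generator draws Poisson(6/h) dive starts per animal-hour,
categories i.i.d. from a mixture that is (0.9, 0.08, 0.02) before the
true changepoint t* = 12 h and (0.5, 0.3, 0.2) after (step transition by
default; an exponential relaxation is available), and lognormal durations
with category medians 120/420/720 s and σ = 0.5 — synthetic defaults
chosen to mimic progressively longer deeper dives, not field
measurements.  Record ends are staggered between 70% and 100% of the
nominal duration so the drop-weighted reference machinery is exercised.
Simulated dives may overlap in time (only start hour, duration and
category enter the analysis); the non-overlap guarantee applies to dive
tables segmented from depth traces.

What the synthetic tests show: both estimators recover their generating
truths at realistic cohort sizes (slopes within 5%, breakpoint intervals
covering t*), the slope test holds its nominal level approximately, and
the breakpoint stage does not invent recoveries under the null.  What
they do not show: robustness to model misspecification — real log-metric
decays need not be linear in 1/(t+1), real dive-category mixtures drift
with foraging context and environment rather than switching cleanly, and
real records contain gaps, sensor dropouts and orientation artifacts that
the generators do not emulate.  The per-group RoR disparity diagnostic
exists precisely because small real cohorts can violate the shared-
baseline assumption.

## Numerical and scale choices

Problem sizes in the test suite are chosen to exercise each estimator at
the scale it targets while keeping the full suite quick: the calibration
tests use 20 seeded replicates for coverage checks, 200 for the level
checks, 200–1000 bootstrap replicates per interval, and the default
100 h × 60 obs/h cohorts for parameter recovery.  Degenerate inputs are
rejected with explicit messages (single distinct time value, non-positive
responses, empty normal region, fewer than three bootstrap blocks);
metric values of exactly zero are dropped before log-scale fitting, as
they carry no multiplicative information.  All estimators are
deterministic given their seed; generators are pure functions of
(scenario, seed).

## Known limitations

* The decay-in-z form imposes monotone recovery; non-monotone responses
  (e.g. delayed stress) are outside the model class.
* The entropy arm needs enough pooled dives per hour (roughly ≥ 20) for
  P_t to be stable; below that the RoR widens until changepoints of
  moderate effect size are undetectable — this is visible in the tests,
  where 3-animal groups cannot resolve a perturbation that 8-animal
  groups resolve comfortably.
* Handling of elevated responses (α > 0) is symmetric by construction;
  if a metric is elevated at one quantile and suppressed at another the
  per-quantile return times remain interpretable but a single "recovery
  time" for the metric is not defined — report the maximum.
* Bootstrap p-values for slope contrasts rely on a normal approximation
  of the bootstrap distribution; with very few animals they are
  approximate (slightly anticonservative in the level check).
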