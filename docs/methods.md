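# Methods

This note documents the models, conventions, and numerical choices behind
`temposelect`, and what the synthetic validation does and does not show.

## Track processing

**Outlier rule.**  A fix is a positional outlier when the implied speed
from the previously retained fix exceeds 15 km per hour (the threshold is
expressed as a distance per interval and scaled to the actual gap).  The
later fix of the offending pair is removed and the scan continues against
the last retained fix, so a single spike costs exactly one fix.  The rule
is applied iteratively within one pass; applying it once versus to
convergence differs only for pathological tracks.

**Regularization.**  Greedy forward scan per individual: a fix is kept
when its gap from the last kept fix lies in [45, 75] min (target 60 ± 15);
any out-of-window gap closes the current burst and the offending fix
anchors the next one.  Bursts shorter than three fixes are dropped because
a turning angle needs two consecutive steps.  The scan is deterministic
and idempotent: re-regularizing an already regular track keeps every fix.

**Step geometry.**  A burst of n fixes yields n − 1 steps and n − 2
turning angles.  Turning angles are signed differences of consecutive
bearings wrapped to (−π, π]; a zero-length previous step leaves the
bearing, and hence the turn, undefined (flagged, excluded from kernel
fitting and random-step generation).

## Movement kernels and random steps

Step lengths get a gamma MLE: the shape solves
log k − ψ(k) = log(mean) − mean(log x) by Newton iteration from the
standard closed-form start, and scale = mean/shape, so shape·scale equals
the sample mean exactly.  Zeros are dropped with a logged count.  Turning
angles get a von Mises MLE: μ is the circular mean and κ solves
A₁(κ) = R̄ (mean resultant length) by Brent's method on [10⁻¹², 10⁶],
using exponentially scaled Bessel functions for stability; R̄ < 10⁻⁸ gives
κ = 0 and R̄ ≈ 1 returns the cap.

Each observed step with a defined previous bearing receives exactly one
random step: length from the fitted gamma, turn from the fitted von Mises
added to the previous bearing.  Endpoints outside the landscape are
redrawn (up to 100 rounds) and finally kept with a flag; in practice the
flag rate is negligible away from the landscape edge.

## Covariates and the conditional logit

Endpoint covariates are read from the raster cell containing the point
under a half-open convention: a cell owns [edge, edge + cell_size) on both
axes, so points on shared edges belong to the higher-index cell.  Habitat
dummies cover deciduous forest, coniferous forest, wetland, grassland and
arable land; road and settlement distances are z-scored with the sample
standard deviation (ddof = 1) pooled over **all** endpoints of the whole
dataset, not per temporal subset — this keeps β comparable across cells,
which the second-stage smoothing requires.

The 1:1 matched conditional likelihood depends only on within-pair
covariate differences d_i = x_obs − x_rand:
ℓ(β) = −Σ log(1 + e^{−β d_i}).  Newton–Raphson starts at 0, caps single
steps at ±5, and declares convergence at |score| < 10⁻⁸ (50 iterations
max); the standard error is the inverse square root of the observed
information.  Pairs with d = 0 are uninformative.  No informative pair →
non-estimable flag.  Complete separation (all informative d of one sign)
→ β reported as sign·10 with a separation flag; flagged fits never enter
the smoothing stage.  For a binary covariate the solution equals
log(a/b), the ratio of discordant-pair counts, which the tests use as an
exact oracle alongside golden-section likelihood maximization and an
independent conditional-logit implementation.

## Temporal grid

Cells are 14-day periods × clock hours.  Period = min(26,
⌊(day_of_year − 1)/14⌋ + 1): since 26 × 14 = 364, days 365–366 are
absorbed into period 26, preserving the 26 × 24 = 624-cell grid.  A pair
is assigned by the observed step's end timestamp (covariates live at step
endpoints).  Cell sample sizes are standardized to 863 pairs (1,726
locations) by uniform sampling of whole pairs without replacement —
strata are never split.  Each cell's subsample seed derives from
(master seed, period, hour), so cell results are independent of iteration
order.  Cells below target follow a policy: `error` or `warn_keep_all`
(default), the latter intended for small simulated datasets.

## Cyclic smoothing

Each model's per-cell β̂ is smoothed with a penalized Gaussian additive
model: intercept + cyclic smooth of hour (period 24, basis dimension
k = 5) + cyclic smooth of the period index (period 26, k = 10) + their
tensor interaction.  Bases are cyclic cubic B-splines built by wrapping
the k + 3 uniform B-splines modulo k, which makes values and derivatives
match across the seam exactly.  Penalties are cyclic second-order
coefficient differences (null space: constants); the interaction penalty
is S_h ⊗ I + I ⊗ S_y in the constrained marginal bases.  Each marginal
smooth is constrained to average zero over its cycle (null-space
reparameterization of the cycle-mean constraint), identifying the
intercept as the surface mean.

The three smoothing parameters are selected by exhaustive GCV over a
fixed log-spaced grid (10⁻³…10⁵, 9 points per term, 729 combinations) —
deterministic by construction; a warning marks an optimum on the grid
boundary.  A 10⁻¹⁰ ridge keeps the system well-posed at λ → 0.  Term edf
is the trace of the corresponding block of (XᵀX + S)⁻¹XᵀX.

Time coordinates use a left-edge convention: the cell (period p, hour h)
sits at (p − 1, h), and prediction maps calendar day d to (d − 1)/14
(clipped so days 365–366 stay inside the period-26 interval) and clock
hour to itself.  Prediction surfaces are evaluated on the 365 × 24 grid.

Term significance uses a permutation test rather than the approximate
F-tests of classical GAM software: the response is permuted across cells,
the model refitted with λ fixed at the selected values, and each term's
explained sum of squares compared with its null distribution;
p = (1 + #{perm ≥ obs})/(n_perm + 1).  The test is exact under
exchangeability; its type-I error is verified by simulation.

## Metrics

* RSS = exp(β); preference = β > 0 (ties count as avoidance — the tie
  rule matters only for exactly-zero surfaces).
* Cumulative selectivity = Σ|β̂| over the five habitat models (distance
  models are on a different scale and excluded); its own smooth uses the
  same machinery with day-of-year mapped to the 26-period cycle.  Values
  above 3.5 are flagged as high selectivity.
* Fold differences are marginal ratios: diel fold = max/min of the hourly
  means across days, seasonal fold = max/min of the daily means across
  hours.  The definition requires a strictly positive surface, so
  per-habitat β surfaces are compared on the RSS scale exp(β̂), while the
  cumulative surface (non-negative by construction) is used directly.
  This marginal-ratio definition is this package's convention; other
  definitions (e.g. pointwise extremes) would give larger folds.
* Repeatability: for each of the 624 cells the 7-vector of smoothed β
  (evaluated at the cell's period-midpoint day and its hour, unscaled) is
  correlated with every other cell's vector — C(624, 2) = 194,376 Pearson
  correlations (Spearman available).  Zero-variance profiles yield
  undefined r and are excluded with a count.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets: hourly
fixes over a full calendar year for multiple individuals, gamma step
lengths (default shape 2, scale 150 m), von Mises turns (default κ = 1),
and a multinomial choice among M = 10 candidate endpoints with weight
exp(Σ_h β_h(day, hour)·x_h).  True coefficient surfaces are first-order
harmonics β(d, t) = a₀ + a_hour·cos(2πt/24 − φ_h) + a_year·cos(2πd/365 −
φ_y) + a_int·cos(2πt/24)·cos(2πd/365) — exactly periodic in both axes and
therefore recoverable by the cyclic smoothers.  Landscapes are
nearest-seed (Voronoi) mosaics of the nine habitat classes with straight
road polylines and clustered settlements; distance grids come from a
Euclidean distance transform.  Boundary handling is redraw-then-reflect,
which keeps the kernel unbiased in the interior.  One global movement
kernel serves all individuals, matching the pooled (not per-individual)
estimation downstream.

What the generator does **not** emulate: home-range fidelity, migration,
inter-individual heterogeneity in selection, GPS positional error,
fix-rate gaps and collar failures, weather, and any correlation between
habitat mosaic and road placement.  Passing recovery tests therefore
show that the estimation chain is correct under its own assumptions, not
that those assumptions hold for any real dataset.

A lightweight pair generator (`make_synthetic_pairs`) draws matched pairs
directly from the conditional choice model in every temporal cell; it is
used where structural properties of the grid are tested and a full
movement simulation would add nothing.

## Validation problem sizes

The recovery experiments use 20 simulated individual-years (≈175,000
pairs, ≈280 pairs per temporal cell, below the 863-pair target, so the
keep-all policy applies), with injected amplitudes of 1.0: seasonal on
deciduous forest, diel on arable land.  Recovered surfaces correlate
above 0.95 with truth at this size; the acceptance threshold is 0.7.
Oracle comparisons use 1,000 binary and 200 continuous datasets; kernel
MLE recovery uses n = 20,000 draws; permutation calibration uses 200
noise datasets with 99 permutations each.

## Known limitations

* Distance-to-road/settlement selection is estimated on the global z
  scale; simulating distance-driven selection couples the covariate to
  landscape geometry and recovery for those two models is not asserted.
* The GCV grid is coarse by design (determinism over precision); edf
  values are comparable across runs but not to REML-based software.
* The conditional logit is single-covariate by construction, mirroring
  the seven-model design; joint multi-covariate SSFs are out of scope.
* The year cycle is the 364-day (26-period) domain; days 365–366 share
  period 26 rather than owning spline support.
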