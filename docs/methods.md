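# Methods

## The statistic and the test

For user *u*, user lift is `lift_u = e_base(u) − e_model(u)`, where both
errors are measured on the same days and in the same units: percent
incorrect for binary state prediction, RMSE in Likert units for level
prediction. The personal-baseline error uses the constant that is optimal
for that user within the metric — the mode of their binary labels for 0-1
loss, the mean of their daily levels for RMSE — so a positive lift cannot be
manufactured by a weak comparator.

The cohort-level question "is the average lift positive?" is answered with a
one-sample sign-flip permutation test. Its null assumes each user's lift is
symmetrically distributed about zero, making the sign exchangeable; the test
statistic is the mean. With *n* users there are 2ⁿ equally likely sign
patterns:

* **n ≤ 20 — exact**: every pattern is enumerated via meet-in-the-middle
  (two arrays of 2^⌊n/2⌋ half-sums and one outer addition), so an n = 20
  exact test costs a 1024 × 1024 array operation. p = #{patterns with mean ≥
  observed} / 2ⁿ. The observed pattern is always counted, so p ≥ 2⁻ⁿ > 0.
* **n > 20 — Monte Carlo**: B seeded sign draws and the standard positively
  biased estimate p = (1 + #{mean ≥ observed}) / (1 + B), which keeps the
  test valid (conservative).

Ties: "≥ observed" is evaluated with a relative tolerance of 1e-9 so that
floating-point reassembly of the observed sum cannot drop the identity
pattern from the tail. All-zero lifts therefore give p = 1. The `≥`
convention also yields the sign-antisymmetry property
p(lifts) + p(−lifts) ≥ 1, with equality up to tie mass.

Descriptive statistics reported alongside the test (mean, quartiles,
5th/95th percentiles) use linear interpolation between order statistics.

## Pipeline stages

**Inclusion filter.** A day qualifies if it has at least one self-report and
≥ 35 GPS observations; a user is retained with ≥ 30 qualifying days. Days
failing the GPS threshold are dropped entirely, not kept label-only. The
day boundary is local civil midnight in a single configurable study timezone
(default UTC) — the target deployments are single-campus studies.

**Labels.** A day's level is the arithmetic mean of that day's reports
(duplicate timestamps both count); the binary label thresholds the mean,
with the threshold value itself assigned to the positive (stressed/happy)
class — on a scale whose threshold step means "a little stressed", that
report *is* a stressed state. The threshold is a required scale parameter
(for symmetric negative-to-positive scales, the midpoint).

**Location preprocessing.** Coordinates are projected to a local planar
frame (equirectangular about the user's median coordinate; < 0.5% distance
error under 50 km spans, warning beyond 500 km). Two clusterings are fitted
per user:

1. *Full clustering*: diagonal-covariance Gaussian mixtures for K = 1…20,
   keeping the minimum-BIC model (ties toward smaller K; K capped at ⌊n/2⌋
   for fewer than 20 samples; `reg_covar = 1e-4` m² floors degenerate
   covariances). Diagonal covariances were chosen over full ones for
   stability on elongated commute traces, and they fix the free-parameter
   count used for the day-level AIC/BIC features at m = (K−1) + 2K + 2K =
   5K − 1.
2. *Stationary clustering*: K-means over stationary samples only. A sample
   is stationary when its speed — consecutive-pair distance over Δt, the
   first sample inheriting the second's state — is below 1 km/h, unless the
   provider supplies a moving flag, which is passed through untouched.
   Coincident timestamps with distinct coordinates are flagged moving and
   counted as anomalies. K is selected by BIC under a shared-variance
   spherical-Gaussian reading of the K-means solution (m = (K−1) + 2K + 1),
   mirroring the full-clustering selection because no canonical rule exists
   for this step; the cap is configurable.

*Semantic clusters*: home = the full-GMM component holding the most samples
at 23:00–06:00 local; work = most samples at 11:00–16:00; night cluster =
stationary cluster with the most samples at 00:00–06:00. Dwell is measured
in sample counts, not interval weights, because observations are
deliberately never interpolated to a regular grid; under regular sampling
the two rules coincide (tested). An empty window leaves the identity
undefined and the matching dwell fraction at 0, flagged.

**Daily features** (for each qualifying day): fraction of samples not
stationary; mean and SD of consecutive-pair displacements, skipping pairs
more than 10 minutes apart so overnight gaps do not dominate; log location
variance ln(var_x + var_y + ε) with ε = 1e-12 m²; circadian movement = the
Euclidean distance between the day's stationary-cluster occupancy vector and
the user's study-long mean occupancy vector (the mean includes the day being
featurized by default — the literal reading — with an `exclude_current_day`
flag for the leakage-free variant); occupancy entropy −Σ p ln p; exact
minimum enclosing circle radius (Welzl's algorithm after a convex-hull
reduction); home/work/night occupancy fractions (assignment by maximum GMM
responsibility / nearest stationary centroid); the day's total log-likelihood
under the user's GMM with the derived AIC = 2m − 2ℓ and BIC = m ln(n_day) −
2ℓ; and counts of distinct full/stationary clusters visited.

**Models.** Binary: L2-penalized logistic regression (liblinear solver —
fastest at these problem sizes), RBF-kernel SVM, random forest. Levels:
elastic net, lasso. A `constant` dummy family exists for testing and as the
single-class fallback. Outer evaluation is leave-one-out; hyperparameters
come from an inner 10-fold grid search over small documented grids
(logistic: 4 C values; SVM: 3 C × 2 γ; elastic net: 3 α × 3 mixing ratios),
by default re-selected inside every outer training set ("nested"), with a
"once" mode that selects a single time on the full training scope.
Standardization statistics are computed on training rows only. Regression
predictions are not clipped to the Likert range by default (`clip_to_scale`
is available). Personal models see only the target user's other days —
enforced by construction and auditable through a training-set hook;
population models pool all users' days, so every user contributes to every
training fold, which is the defining property of that scope. Baselines are
evaluated in-sample (a constant guess has nothing to overfit); a
leave-one-out baseline mode exists for strict comparability but is off by
default.

## The synthetic cohort generator

The generator emulates the statistical structure the evaluation framework
assumes, with ground truth retained for recovery tests. Each user has
`n_locations_per_user` planar sites (home; work 2–6 km away; extras within
~3 km). Each day is an hourly dwell schedule — 23:00–06:00 home with
probability 0.92, 11:00–16:00 work with probability 0.85, other hours sticky
random — with ±10-minute jitter at transitions and 10-minute linear travel
segments (flagged moving) between sites. GPS fixes are drawn uniformly over
the day and perturbed with isotropic noise (default 20 m); coordinates are
emitted as lat/lon via the inverse equirectangular map.

Daily state: `level_ud = clamp(round(μ_u + β·s_ud + ε_ud))` with μ_u ~
N(scale midpoint, between_user_sd = 1.0) clamped, ε_ud ~ N(0, within_user_sd
= 0.7), and s_ud the within-user z-score of the fraction of the day spent
away from home — itself (the complement of) one of the extracted features,
so β > 0 plants a signal the models can genuinely learn, while β = 0 makes
labels exactly independent of GPS. Reports (2/day) add integer-rounded N(0,
0.5) noise, clamped to the scale. The default variance configuration
(within 0.7 vs between 1.0 on a 5-point scale) encodes the regime the
framework targets — users far less variable day-to-day than the cohort is
across users — the field reports this qualitatively but publishes no numeric
ratio, so the value is this package's choice, fixed once.

What the generator does **not** emulate: heavy-tailed human displacement
(Lévy-like excursions), weekly seasonality, informative missingness, scale
anchoring drift. Passing the batteries therefore shows the machinery is
correct and calibrated under the assumed structure, not that any particular
real cohort satisfies that structure.

## Evaluation scale of the repeated-cohort batteries

The null-calibration and power batteries run 50 independent cohorts of 20
users × 40 days each (35 GPS fixes/day), the size regime of the target
studies. Per-cohort settings are chosen for desk turnaround: cluster search
capped at K ≤ 6 (the generator plants 4 sites), single GMM initialization,
one fast model family (L2 logistic), hyperparameters selected once per
training scope. Signal cohorts use β = 1.5 — about two within-user SDs per
SD of mobility, a deliberately strong planted effect, since the power
criterion asks whether the pipeline detects a real signal, not its detection
threshold. The type-I calibration battery (1,000 replicates of 20
standard-normal lifts) uses the exact test throughout and checks the
rejection rate against the exact binomial 99% interval around α = 0.05.

## Numerical choices and degenerate inputs

* Minimum enclosing circle: Welzl's move-to-front algorithm on the convex
  hull (the optimal circle depends only on hull points); collinear triples
  fall back to the best two-point circle; containment tolerance 1e-7
  relative. Verified exactly against a brute-force candidate-circle oracle
  and against an independent geometry library.
* Zero-variance days: log location variance floors at ln(ε); displacement
  features are 0 when no valid pair exists; entropy of a single-cluster day
  is 0.
* Mode ties (baselines, constant fallback) break toward the negative class,
  deterministically; family-selection ties break toward the simpler family
  in a documented order; BIC ties toward smaller K.
* All stochastic components (generator, GMM/K-means restarts, fold shuffles,
  Monte-Carlo tests) consume explicit seeds; batteries derive per-cohort
  seeds from a root seed via seed sequences, keeping cohorts independent but
  reproducible.

## Known limitations

* The sign-flip null assumes symmetric lifts; under asymmetric nulls the
  test is only approximately level (the usual caveat for this test class).
* The "once" hyperparameter mode lets the selection see the held-out day's
  training folds; the nested default does not. The batteries use "once" and
  rely on the null battery itself to confirm this does not inflate lift.
* Circadian movement's default reference distribution includes the
  featurized day (the literal definition); switch on `exclude_current_day`
  for leakage-free feature construction.
* Population-model LOOCV refits per held-out observation and is expensive at
  cohort scale; it is off by default in the pipeline driver and exercised at
  small sizes in the tests.
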