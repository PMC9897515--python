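# Methods

## The model

A movement recording is a multivariate time series sampled at 100 Hz with
K = 15 channels: 3-axis accelerometer (`acc`), 3-axis gyroscope (`gyr`),
3-D marker position (`p0`) and its first and second Savitzky–Golay
derivatives (`p1`, `p2`; window 17 samples, cubic fit, scaled by the sample
rate so they are per-second quantities).  Channels are z-scored with
statistics pooled over every recording of a dataset, template included, so
that distances are comparable across pairs and held-out data can be
transformed with the same statistics (the `{channel: (mean, std)}` table is
returned for audit).

The baseline dissimilarity between the template T and a performance A is
dynamic time warping with an L1 element-wise cost,

    DTW(T, A) = Σ_{i∈p} ‖t_{i(0)} − a_{i(1)}‖₁ ,

where p is the optimal monotone, boundary-anchored alignment path.  Two
parameterised variants carry the interpretable weights:

* **channel weighting** — cost Σ_k w_k |t^k − a^k| with w_k > 0 and
  (1/K) Σ w_k = 1;
* **segment weighting** — the *unweighted* path is computed first, then
  partitioned into N contiguous blocks of (near-)equal size on the
  template's own index axis, and the distance is Σ_j w_j · (block-j partial
  sum) with w_j > 0, Σ w_j = 1.  Defining blocks on the template axis makes
  the operation asymmetric by construction, but gives every performance the
  same, comparable segmentation.

Human annotations are *relative* similarity ratings: for a pair (A, A′) of
performances by the same learner from different sessions, a value in
[−1, 1], −1 meaning A is closest to the template.  The model score of a
pair is the difference of weighted distances,
m(A, A′) = DTW_w(T, A) − DTW_w(T, A′), assumed linearly related to the
rating.  Weights are estimated by minimising the mean squared error between
affinely calibrated scores (gain · m + offset) and ratings, and the quality
of a weight vector is reported as the Pearson correlation between scores
and ratings (the calibration does not affect it).

## Numerical choices

* **Approximate alignment.**  Long recordings are aligned with the
  multilevel coarsen–project–refine scheme: both series are recursively
  halved (adjacent-sample means), the coarse pair aligned, and the dynamic
  program re-run inside a corridor of `radius` cells (default 10) around
  the projected coarse path.  The result is the cost of a feasible path, so
  it never undercuts the exact optimum; a radius at least the length of
  both series falls back to exact dynamic programming, which is what every
  oracle-equivalence test uses.  Dynamic-programming ties are broken
  deterministically: diagonal first, then the step advancing the template
  index.  Kernels are numba-compiled.
* **Optimisation.**  The fixed-path score is linear in the weights, and the
  calibration gain absorbs their overall scale, so the feasible set
  (positive normalised weights × gain) maps exactly onto the positive
  orthant of β = gain·w.  L-BFGS-B therefore runs on the equivalent convex
  box-constrained least-squares problem in (β, offset) with analytic
  gradients and columns pre-scaled to unit baseline-score variance; the
  direct product parameterisation is badly conditioned on collinear delta
  matrices and can trigger the stopping rule almost immediately.  The
  stopping rule is a relative loss change below 1e−3; the returned gain and
  offset are the exact least-squares calibration at the final weights, and
  the normalisation (mean one for channels, sum one for segments) is exact
  in the reported weights.  Inside the optimiser the baseline (unweighted)
  path is reused, which matches the segment-mode definition exactly and
  makes the channel-mode loss linear; `dtw_feature` also offers full
  re-alignment per weight setting (`path_policy="realign"`), and the two
  agree at uniform weights.
* **Cross-validation** splits *participants*, never pairs: repeated 2-fold
  over the 12 learners, 8 repeats, giving 16 fold estimates, reported as
  mean (SD) of the held-out Pearson correlation.  Degenerate folds
  (constant training ratings or fewer than 2 test pairs) are flagged
  invalid and skipped with a warning rather than crashing.
* **Equal-size segmentation** distributes a non-zero remainder to the
  earliest blocks, one extra template index each — any fixed rule works;
  this one is reproducible.
* **Exponential learning curves** are fitted as y = a·exp(b·x) + c by
  nonlinear least squares with a ≥ 0 and c ≥ 0 (alignment errors cannot be
  negative; without the floor bound, b and c trade off freely on weakly
  curved series and the rate estimate is erratic), initialised from a
  log-linear regression which also serves as the fallback when the
  nonlinear fit fails.  The rate coefficient is b; more negative means
  faster improvement.  Curves are fitted on errors averaged over
  participants at each (session, trial) practice rank; fitting per
  participant and averaging coefficients is a reasonable alternative we did
  not take.
* The ICC forms are the two-way, absolute-agreement ones (McGraw–Wong):
  ICC(A,1) for a single rating, ICC(A,k) for the k-rater mean, computed
  from the ANOVA mean squares with exact F-based 95% intervals
  (Satterthwaite degrees of freedom) and the between-pair F test on
  (n−1, (n−1)(k−1)) degrees of freedom.  The inter- vs intra-rater
  comparison is a Welch t-test on per-pair rating SDs — a reconstruction of
  an agreement comparison from summary scores, not an ICC-difference test.

## What the simulator emulates

The generator produces the statistical structure the method assumes, with
known ground truth, at the study's scale: 12 learners, 3 sessions, 8 trials
per session, a 12-s four-phrase template, 180 within-learner cross-session
rated pairs, single rater with noise σ_r = 0.1.

* **Template**: cubic-spline horizontal arcs with two Gaussian vertical
  strokes per phrase, small depth excursion (x–y dominated); p1/p2 are the
  exact derivatives of the generating function; accelerometer = p2 plus a
  slowly rotating gravity-like term and bias; gyroscope = a smoothed
  (v × a)/|v|² angular-velocity proxy.  Deterministic given the
  configuration.
* **Performances**: template + per-channel smooth error fields (Gaussian
  noise, ~0.3 s correlation length) whose magnitude is
  E₀·exp(−r_k·τ) + floor in channel-SD units, τ counting performed trials
  (massed practice), with lognormal per-performance amplitude jitter
  (σ = 0.55 — trial-to-trial variability is the sole source of per-channel
  identifiability, and a CV near 0.6 is realistic for motor learning);
  extra structured error inside the designated salient template spans
  (segments 17–20 of 25), decaying faster than the average channel
  (0.3/trial) above a persistent floor; and a smooth monotone time warp
  whose strength decays with practice.
* **Raters**: the latent pair score is the ground-truth weighted-DTW
  difference (channel weights w*, or segment weights concentrated 70% on
  the salient segments, per the configured rating basis), mapped into
  [−1, 1] by a linear gain set from the 99th percentile of |score| (so the
  assumed linearity holds in-range, with ~1% clipping), plus i.i.d.
  Gaussian rater noise, clipped.
* **Ground-truth coupling**: per-channel learning rates follow the rank
  order of w*, spread over [0.04, 0.4] per trial — distinguishable from one
  another yet slow enough that between-session differences persist for
  raters to judge; the salient segments likewise learn faster than average.
  This realises the hypothesis under test (what raters attend to is where
  learning happens), so recovered weight–rate correlations are negative by
  construction.

**What it does not emulate** — and hence what passing tests do not show
about real data: biomechanics (no joint or orientation model; warping
breaks exact derivative consistency between position and its channels),
rater idiosyncrasy beyond i.i.d. noise, non-exponential learning (plateaus,
warm-up, forgetting between sessions), and realistic rating noise levels:
with σ_r = 0.1 the simulated rating–distance correlations sit near 0.97,
far above what human raters produce, so absolute correlation levels here
say nothing about attainable levels on real recordings.  One consequence:
because correlations are nearly saturated and the salient span [0.64, 0.80)
of the template is almost representable by block 4 of a 5-segment model,
the cross-validated sweep often peaks at coarse N rather than at the true
granularity 25 — the qualitative ordering (N = 25 beating both N = 2 and
N = 80) is reproduced, the exact peak location is not guaranteed.

## Known limitations

* Equal-size partitions at different segment counts are **not nested**
  (boundaries of N = 5 are not a subset of N = 7), so the training
  correlation is not mathematically guaranteed to be monotone in N;
  observed violations of a few 1e−3, with the fitted optimum verified equal
  to the exact constrained optimum, are a property of the model family, not
  of the optimiser.  Monotonicity does hold along divisor chains.
* The approximate alignment with radius 10 is treated as *the* path for
  segmentation and error decomposition; all conservation identities are
  exact with respect to that path.
* `compare_reliability` degrees of freedom follow Welch–Satterthwaite on
  the per-pair scores; with designs of 90 and 45 pairs this lands near the
  t(131) regime of complete two-sample comparisons but is not a claim about
  any particular published test.
* Feature-mode weighted distances with `realign` are not used inside the
  optimiser; if the true generating process re-aligned per weight setting,
  fixed-path fitting is an approximation (both policies are exposed).
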