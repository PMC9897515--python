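# movemetric

Learning interpretable weighted Dynamic-Time-Warping similarity metrics
from human ratings of movement similarity, for motor-learning analysis.

## The problem

When people learn a complex gesture by imitating a video template, judging
how close a performance is to the template is something humans do easily
but computational metrics do only approximately.  `movemetric` bridges the
two: given relative similarity ratings — for a pair of performances
(A, A′) by the same learner from different practice sessions, a value in
[−1, 1] saying which is closer to the template T — it learns the weights of
a DTW-based distance so that distance differences match the ratings, and
then interprets those weights against where and on which movement features
motor learning actually happened.  It is written for researchers in
human-movement science and embodied interaction who have multivariate
recordings (motion capture + IMU) and pairwise human judgements.

## The model

A recording is a K-channel time series (K = 15: 3-axis accelerometer,
3-axis gyroscope, 3-D position and its first two Savitzky–Golay
derivatives, each channel z-scored with statistics pooled over the
dataset).  The baseline distance is DTW with an L1 element-wise cost over
the optimal monotone path p:

    DTW(T, A) = Σ_{i∈p} ‖t_{i(0)} − a_{i(1)}‖₁

Two weighted variants are learned:

* channel weights:  DTW_feature(T, A) = Σ_{i∈p} Σ_k w_k |t_{i(0)}^k − a_{i(1)}^k|,
  with w_k > 0 and (1/K) Σ_k w_k = 1;
* segment weights:  the unweighted path is partitioned into N equal blocks
  of template indices, and DTW_segment(T, A) = Σ_j w_j Σ_{i∈p_j} ‖·‖₁,
  with w_j > 0 and Σ_j w_j = 1.

The model score of a rated pair is m(A, A′) = DTW_w(T, A) − DTW_w(T, A′).
Weights are fitted with L-BFGS-B by minimising the MSE between affinely
calibrated scores and ratings (convergence: relative loss change < 1e−3),
and evaluated as the Pearson correlation between scores and ratings under
participant-wise repeated 2-fold cross-validation (8 repeats → 16
estimates).  Learned weights are then compared with per-channel and
per-segment motor-learning rates — the coefficient b of an exponential
a·exp(b·x) + c fitted to alignment errors over practice time — where a
negative weight–rate correlation means raters attended to the features and
moments where most learning happened.

Long alignments use the multilevel coarsen/refine DTW approximation
(radius 10 by default); exact dynamic programming is used whenever the
radius covers both series.  Inter- and intra-rater agreement is quantified
with two-way absolute-agreement intraclass correlations, ICC(A,1) and
ICC(A,k).

A built-in simulator generates study-scale synthetic datasets (12
learners, 3 sessions, a 12-s four-phrase planar gesture, 180 rated pairs)
with known ground-truth weights, salient segments and learning rates, so
the whole pipeline is testable without any recordings.

## Worked example

```python
import numpy as np
from scipy.stats import pearsonr
from movemetric import (SimConfig, make_dataset, compute_pair_deltas,
                        fit_weights, CVPlan, cross_validate)

cfg = SimConfig(seed=42)                      # 12 learners, 180 rated pairs
dataset, truth = make_dataset(cfg)

deltas = compute_pair_deltas(dataset)         # one alignment per recording
fit = fit_weights(deltas.channel_deltas, deltas.ratings, mode="feature")
print(f"training correlation: {fit.train_corr:.3f}")

recovery = pearsonr(fit.weights.values, np.array(truth.feature_weights))[0]
print(f"recovery of planted channel weights: r = {recovery:.3f}")

plan = CVPlan(participants=dataset.participants, seed=0)
folds = cross_validate(dataset, "feature", plan, pair_deltas=deltas)
test = [f.test_corr for f in folds if f.valid]
print(f"held-out correlation: {np.mean(test):.3f} ({np.std(test):.3f}) "
      f"over {len(test)} folds")
```

prints

```
training correlation: 0.955
recovery of planted channel weights: r = 0.798
held-out correlation: 0.939 (0.010) over 16 folds
```

The training correlation is the Pearson r between calibrated weighted-DTW
differences and the simulated ratings on all 180 pairs; the recovery line
says the fitted channel weights reproduce the simulator's ground-truth
weights up to r ≈ 0.8; the last line is the cross-validated correlation on
held-out participants, mean (SD) over the 16 fold estimates.

The same workflow is available from the shell:

```
movemetric simulate --out data/sim --seed 1
movemetric cv --dataset data/sim --mode feature
movemetric sweep-segments --dataset data/sim
movemetric learning-rates --dataset data/sim --by feature
movemetric reliability --ratings data/sim/ratings.csv
```

Each invocation writes its artifacts and a manifest (config, seeds,
package version, input hashes) into a fresh run directory.

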