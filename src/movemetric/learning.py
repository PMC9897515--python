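"""Fitting DTW weights so distance differences match similarity ratings.

For a rated pair (A, A') the model score is

    m_optim(A, A') = DTW_optim(T, A) - DTW_optim(T, A')

where DTW_optim is the feature- or segment-weighted distance.  Weights are
found by minimising the mean squared error between affinely calibrated
scores (gain * m_optim + offset) and the human ratings with L-BFGS-B,
subject to strictly positive weights and the mode's normalisation (channel
weights average to one, segment weights sum to one).  Ratings live in
[-1, 1] while DTW differences are unbounded, so the two calibration
parameters make the MSE well-posed; they do not affect the reported Pearson
correlations.  Because the segment-weighted distance (and the fixed-path
feature-weighted distance) is linear in the weights, per-pair per-unit error
differences are precomputed once and every optimiser evaluation is a matrix
product.

Evaluation uses a repeated participant-wise K-fold plan (default K=2, 8
repeats, i.e. 16 fold estimates): all pairs of a participant stay on one
side of each split, preventing identity leakage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .dtw import (AlignmentPath, WeightVector, dtw, per_channel_errors,
                  per_segment_errors)
from .io import FeatureSet, MovementSeries, RatingRecord

logger = logging.getLogger(__name__)

#: segment counts swept in the temporal analysis
SEGMENT_SWEEP_N = (2, 5, 7, 12, 15, 20, 25, 30, 40, 50, 80)

#: feature combinations of the baseline grid search
BASELINE_COMBOS = (
    FeatureSet(("acc",)), FeatureSet(("gyr",)), FeatureSet(("p0",)),
    FeatureSet(("p1",)), FeatureSet(("p2",)),
    FeatureSet(("acc", "gyr", "p0")), FeatureSet(("p0", "p1", "p2")),
    FeatureSet(("acc", "gyr", "p0", "p1", "p2")),
)

MovementKey = tuple[str, int, int]  # (participant, session, trial)


class DegenerateTargetError(ValueError):
    """Raised when the rating targets carry no usable variance."""


@dataclass
class MovementDataset:
    """A template, its performances, and rated performance pairs.

    ``pairs`` resolves each rated pair id to the recording keys of A and A'.
    Series are expected to be preprocessed consistently (same channels,
    shared standardisation) before distance computations.
    """

    template: MovementSeries
    movements: dict[MovementKey, MovementSeries]
    ratings: list[RatingRecord]
    pairs: dict[str, tuple[MovementKey, MovementKey]]

    def __post_init__(self):
        missing = [pid for r in self.ratings if (pid := r.pair_id) not in self.pairs]
        if missing:
            raise KeyError(f"ratings reference unknown pair ids: {missing[:5]}")

    @property
    def participants(self) -> list[str]:
        return sorted({k[0] for k in self.movements})

    def pair_series(self, pair_id: str):
        ka, kb = self.pairs[pair_id]
        return self.movements[ka], self.movements[kb]


@dataclass
class PairScore:
    pair_id: str
    delta: float   # DTW(T, A) - DTW(T, A'); negative when A is closer to T
    rating: float


@dataclass
class FitResult:
    """One fitted weight vector with its training/test diagnostics."""

    weights: WeightVector
    gain: float
    offset: float
    train_corr: float
    test_corr: float = float("nan")
    loss_trace: list[float] = field(default_factory=list)
    converged: bool = True
    valid: bool = True
    fold_id: tuple[int, int] = (0, 0)
    n_train: int = 0
    n_test: int = 0


@dataclass
class CVPlan:
    """Repeated participant-wise K-fold assignments (deterministic by seed)."""

    participants: list[str]
    n_folds: int = 2
    n_repeats: int = 8
    seed: int = 0
    assignments: list[list[list[str]]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.participants) < self.n_folds:
            raise ValueError("need at least one participant per fold")
        if not self.assignments:
            rng = np.random.default_rng(self.seed)
            for _ in range(self.n_repeats):
                order = list(rng.permutation(self.participants))
                folds = [sorted(order[f::self.n_folds])
                         for f in range(self.n_folds)]
                self.assignments.append(folds)

    def folds(self):
        """Yield (repeat, fold, train_participants, test_participants)."""
        for rep, folds in enumerate(self.assignments):
            for f, test in enumerate(folds):
                train = sorted(set(self.participants) - set(test))
                yield rep, f, train, test


# ---------------------------------------------------------------------------
# per-pair linear features (baseline alignments are computed once)
# ---------------------------------------------------------------------------

@dataclass
class PairDeltas:
    """Per-pair differences of per-unit alignment errors, linear in weights.

    ``channel_deltas[i, k]`` is the channel-k error of pair i's movement A
    along its baseline path minus the same quantity for A'.  The baseline
    (unweighted) score of pair i is the row sum.  ``segment_deltas(n)``
    yields the analogous per-segment matrix for a given segment count.
    """

    pair_ids: list[str]
    participant_ids: list[str]
    ratings: np.ndarray
    channel_deltas: np.ndarray
    _dataset: MovementDataset
    _paths: dict[MovementKey, AlignmentPath]
    _segment_cache: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def baseline(self) -> np.ndarray:
        return self.channel_deltas.sum(axis=1)

    def segment_deltas(self, n_segments: int) -> np.ndarray:
        if n_segments not in self._segment_cache:
            ds = self._dataset
            per_mov: dict[MovementKey, np.ndarray] = {}
            for key, path in self._paths.items():
                per_mov[key] = per_segment_errors(
                    ds.template, ds.movements[key], path, n_segments)
            rows = [per_mov[ds.pairs[p][0]] - per_mov[ds.pairs[p][1]]
                    for p in self.pair_ids]
            self._segment_cache[n_segments] = np.asarray(rows)
        return self._segment_cache[n_segments]

    def rows_for(self, participants) -> np.ndarray:
        members = set(participants)
        return np.array([p in members for p in self.participant_ids])


def compute_pair_deltas(dataset: MovementDataset, radius: int = 10,
                        records: list[RatingRecord] | None = None) -> PairDeltas:
    """Align every rated movement to the template once and tabulate deltas."""
    records = dataset.ratings if records is None else records
    needed = sorted({k for r in records for k in dataset.pairs[r.pair_id]})
    missing = [k for k in needed if k not in dataset.movements]
    if missing:
        raise KeyError(f"missing recordings for rated pairs: {missing[:5]}")
    paths: dict[MovementKey, AlignmentPath] = {}
    errors: dict[MovementKey, np.ndarray] = {}
    for key in needed:
        mov = dataset.movements[key]
        _, path = dtw(dataset.template, mov, radius=radius)
        paths[key] = path
        errors[key] = per_channel_errors(dataset.template, mov, path)
    rows = [errors[dataset.pairs[r.pair_id][0]]
            - errors[dataset.pairs[r.pair_id][1]] for r in records]
    return PairDeltas(
        pair_ids=[r.pair_id for r in records],
        participant_ids=[r.participant_id for r in records],
        ratings=np.array([r.rating for r in records]),
        channel_deltas=np.asarray(rows),
        _dataset=dataset, _paths=paths,
    )


def score_pairs(template: MovementSeries, pairs, w: WeightVector | None = None,
                mode: str = "baseline", radius: int = 10,
                path_policy: str = "reuse-baseline-path") -> list[PairScore]:
    """Score rated pairs (A, A', record) with the requested DTW variant."""
    from .dtw import dtw_feature, dtw_segment

    out = []
    for a, b, record in pairs:
        if mode == "baseline":
            da, _ = dtw(template, a, radius=radius)
            db, _ = dtw(template, b, radius=radius)
        elif mode == "feature":
            da = dtw_feature(template, a, w, path_policy=path_policy,
                             radius=radius)
            db = dtw_feature(template, b, w, path_policy=path_policy,
                             radius=radius)
        elif mode == "segment":
            da = dtw_segment(template, a, w, radius=radius)
            db = dtw_segment(template, b, w, radius=radius)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out.append(PairScore(record.pair_id, float(da - db), record.rating))
    return out


# ---------------------------------------------------------------------------
# constrained fitting
# ---------------------------------------------------------------------------

def _normalise(v: np.ndarray, mode: str):
    scale = v.mean() if mode == "feature" else v.sum()
    return v / scale, scale


def _affine_lstsq(s: np.ndarray, r: np.ndarray):
    """Exact least-squares gain/offset for r ~ gain * s + offset."""
    var = s.var()
    if var < 1e-300:
        return 0.0, float(r.mean())
    gain = float(np.cov(s, r, bias=True)[0, 1] / var)
    return gain, float(r.mean() - gain * s.mean())


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(pearsonr(x, y)[0])


def fit_weights(deltas: np.ndarray, ratings: np.ndarray, mode: str,
                init: WeightVector | None = None, tol: float = 1e-3,
                max_iter: int = 1000) -> FitResult:
    """Fit positive normalised weights minimising calibrated-score MSE.

    ``deltas`` is the (n_pairs, n_units) matrix of per-unit error
    differences; the model score of pair i is ``deltas[i] @ w``.  Because
    the calibration gain absorbs the weights' overall scale, the product
    ``beta = gain * w`` ranges over the positive orthant exactly as
    (w, gain) range over the constraint set, so the optimiser works on the
    equivalent box-constrained convex problem in (beta, offset) — L-BFGS-B
    with analytic gradients on a quadratic, which converges reliably where
    the raw product parameterisation is badly conditioned.  The columns are
    pre-scaled to unit baseline-score variance, positivity is enforced by
    the box bounds, and the mode's normalisation (mean one for channels,
    sum one for segments) is applied when the weights are read back out;
    the loss is identical at every step.  Convergence follows the
    relative-loss-change rule (change < ``tol``); the returned gain and
    offset are the exact least-squares calibration at the final weights.
    """
    deltas = np.asarray(deltas, dtype=np.float64)
    ratings = np.asarray(ratings, dtype=np.float64)
    n_pairs, n_units = deltas.shape
    if n_pairs < 2:
        raise DegenerateTargetError(f"need >= 2 pairs, got {n_pairs}")
    if np.ptp(ratings) == 0:
        raise DegenerateTargetError("ratings are constant")

    if init is None:
        init = WeightVector.uniform(n_units, mode)
    w0, _ = _normalise(np.maximum(init.values, 1e-6), mode)
    sigma = (deltas @ w0).std()
    if sigma < 1e-300:
        sigma = 1.0
    d = deltas / sigma
    g0, c0 = _affine_lstsq(d @ w0, ratings)
    # the positive orthant covers gain > 0; flip the design if the initial
    # relation is inverted so the cone is on the informative side
    sign = -1.0 if g0 < 0 else 1.0
    d = sign * d
    beta0 = max(abs(g0), 1e-3) * w0
    theta0 = np.concatenate([beta0, [c0]])

    def objective(theta):
        b, c = theta[:n_units], theta[-1]
        e = d @ b + c - ratings
        loss = float(e @ e) / n_pairs
        grad = np.concatenate([(2.0 / n_pairs) * (d.T @ e),
                               [2.0 / n_pairs * e.sum()]])
        return loss, grad

    trace: list[float] = [objective(theta0)[0]]

    def callback(theta):
        loss = objective(theta)[0]
        logger.debug("iter %d: loss %.6g", len(trace), loss)
        trace.append(loss)

    bounds = [(1e-9, None)] * n_units + [(None, None)]
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   bounds=bounds, callback=callback,
                   options={"ftol": tol * max(trace[0], 1e-12),
                            "maxiter": max_iter})
    theta = res.x if res.fun <= trace[0] else theta0
    converged = bool(res.success)
    if not res.success and res.fun > trace[0]:
        warnings.warn("optimiser failed to improve; returning initial weights")

    w, _ = _normalise(theta[:n_units], mode)
    s = deltas @ w
    gain, offset = _affine_lstsq(s, ratings)  # exact final calibration
    return FitResult(
        weights=WeightVector(w, mode), gain=gain, offset=offset,
        train_corr=_safe_pearson(s, ratings), loss_trace=trace,
        converged=converged, n_train=n_pairs,
    )


# ---------------------------------------------------------------------------
# cross-validation, segment sweep, baseline grid
# ---------------------------------------------------------------------------

def _delta_matrix(pair_deltas: PairDeltas, mode: str,
                  n_segments: int | None) -> np.ndarray:
    if mode == "feature":
        return pair_deltas.channel_deltas
    if mode == "segment":
        if n_segments is None:
            raise ValueError("segment mode needs n_segments")
        return pair_deltas.segment_deltas(n_segments)
    raise ValueError(f"unknown mode {mode!r}")


def cross_validate(dataset: MovementDataset, mode: str, plan: CVPlan,
                   n_segments: int | None = None, radius: int = 10,
                   tol: float = 1e-3,
                   pair_deltas: PairDeltas | None = None) -> list[FitResult]:
    """Fit weights per fold and evaluate the Pearson r on held-out pairs."""
    if pair_deltas is None:
        pair_deltas = compute_pair_deltas(dataset, radius=radius)
    deltas = _delta_matrix(pair_deltas, mode, n_segments)
    results = []
    for rep, f, train, test in plan.folds():
        tr = pair_deltas.rows_for(train)
        te = pair_deltas.rows_for(test)
        if te.sum() < 2 or tr.sum() < 2 or np.ptp(pair_deltas.ratings[tr]) == 0:
            warnings.warn(f"fold (repeat={rep}, fold={f}) is degenerate; skipped")
            results.append(FitResult(
                weights=WeightVector.uniform(deltas.shape[1], mode),
                gain=0.0, offset=0.0, train_corr=float("nan"),
                valid=False, fold_id=(rep, f)))
            continue
        fit = fit_weights(deltas[tr], pair_deltas.ratings[tr], mode, tol=tol)
        fit.fold_id = (rep, f)
        fit.n_test = int(te.sum())
        fit.test_corr = _safe_pearson(deltas[te] @ fit.weights.values,
                                      pair_deltas.ratings[te])
        results.append(fit)
    return results


def _fold_summary(results: list[FitResult]):
    train = np.array([r.train_corr for r in results if r.valid])
    test = np.array([r.test_corr for r in results if r.valid])
    return (float(np.nanmean(train)), float(np.nanstd(train)),
            float(np.nanmean(test)), float(np.nanstd(test)))


def baseline_correlations(pair_deltas: PairDeltas, plan: CVPlan):
    """Unweighted-DTW rating correlation per fold (train and test sides)."""
    rows = []
    base = pair_deltas.baseline
    for rep, f, train, test in plan.folds():
        tr = pair_deltas.rows_for(train)
        te = pair_deltas.rows_for(test)
        rows.append((_safe_pearson(base[tr], pair_deltas.ratings[tr]),
                     _safe_pearson(base[te], pair_deltas.ratings[te])))
    return np.asarray(rows)


def sweep_segments(dataset: MovementDataset, plan: CVPlan,
                   n_list=SEGMENT_SWEEP_N, radius: int = 10, tol: float = 1e-3,
                   pair_deltas: PairDeltas | None = None) -> pd.DataFrame:
    """Cross-validated correlation versus segment count, plus the baseline."""
    if max(n_list) > dataset.template.n_samples:
        raise ValueError("segment count exceeds template length")
    if pair_deltas is None:
        pair_deltas = compute_pair_deltas(dataset, radius=radius)
    base = baseline_correlations(pair_deltas, plan)
    rows = []
    for n in n_list:
        res = cross_validate(dataset, "segment", plan, n_segments=n,
                             radius=radius, tol=tol, pair_deltas=pair_deltas)
        tr_mu, tr_sd, te_mu, te_sd = _fold_summary(res)
        rows.append({"n_segments": n, "train_mean": tr_mu, "train_sd": tr_sd,
                     "test_mean": te_mu, "test_sd": te_sd,
                     "baseline_train_mean": float(np.nanmean(base[:, 0])),
                     "baseline_test_mean": float(np.nanmean(base[:, 1])),
                     "baseline_test_sd": float(np.nanstd(base[:, 1]))})
    return pd.DataFrame(rows)


def baseline_grid(dataset: MovementDataset, plan: CVPlan,
                  combos=BASELINE_COMBOS, radius: int = 10) -> pd.DataFrame:
    """Unweighted-DTW correlation per input feature combination.

    Each combination re-aligns the recordings using only its channels (the
    alignment path depends on the channel subset), then cross-validates the
    Pearson correlation between baseline score differences and ratings.
    """
    rows = []
    for combo in combos:
        sub = MovementDataset(
            template=dataset.template.select(combo.channels),
            movements={k: m.select(combo.channels)
                       for k, m in dataset.movements.items()},
            ratings=dataset.ratings, pairs=dataset.pairs)
        pd_sub = compute_pair_deltas(sub, radius=radius)
        base = baseline_correlations(pd_sub, plan)
        rows.append({"features": str(combo),
                     "test_mean": float(np.nanmean(base[:, 1])),
                     "test_sd": float(np.nanstd(base[:, 1])),
                     "train_mean": float(np.nanmean(base[:, 0]))})
    return pd.DataFrame(rows)
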