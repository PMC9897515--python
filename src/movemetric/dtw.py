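"""Dynamic time warping with L1 costs, feature weighting and segment weighting.

The baseline distance between a template T and a movement A is the sum of
element-wise L1 distances along the optimal monotone alignment path

    DTW(T, A) = sum_{i in p} || t_{i(0)} - a_{i(1)} ||_1 .

Two parameterised variants are provided.  Feature weighting multiplies each
channel's absolute difference by a per-channel weight w_k (w_k > 0, mean 1).
Segment weighting first computes the baseline path, partitions it into
blocks of template indices of (near-)equal size, and weights each block's
partial contribution by w_j (w_j > 0, sum 1).  The segmentation is defined
on the template's own index axis, so two movements aligned to the same
template have directly comparable segments.

For long recordings the path is found with the multilevel
coarsen-project-refine approximation (recursively halve both series, align
the coarse pair, then re-run the dynamic program inside a corridor of the
given ``radius`` around the projected coarse path).  The approximate
distance is the cost of a feasible path and therefore never undercuts the
exact optimum.  A radius at least as large as both lengths falls back to
exact dynamic programming.

Dynamic-programming tie-break: prefer the diagonal step, then the step that
advances the template index, which makes paths deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .io import MovementSeries


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AlignmentPath:
    """Monotone index pairing (template index, movement index) from DTW."""

    steps: np.ndarray  # (L, 2) int64
    n_template: int
    n_movement: int

    def __post_init__(self):
        self.steps = np.asarray(self.steps, dtype=np.int64)
        s = self.steps
        if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 1:
            raise ValueError("path must be an (L, 2) index array")
        if tuple(s[0]) != (0, 0):
            raise ValueError("path must start at (0, 0)")
        if tuple(s[-1]) != (self.n_template - 1, self.n_movement - 1):
            raise ValueError("path must end at (N-1, M-1)")
        d = np.diff(s, axis=0)
        if d.size and not ((d >= 0).all() and (d <= 1).all() and (d.sum(1) >= 1).all()):
            raise ValueError("path steps must advance monotonically by 0 or 1")

    def __len__(self) -> int:
        return self.steps.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["template_index", "movement_index"])


@dataclass
class WeightVector:
    """Nonnegative weights over channels (mean 1) or segments (sum 1)."""

    values: np.ndarray
    mode: str  # "feature" | "segment"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.mode not in ("feature", "segment"):
            raise ValueError(f"unknown weight mode {self.mode!r}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("weights must be a non-empty vector")

    @classmethod
    def uniform(cls, n: int, mode: str) -> "WeightVector":
        v = np.ones(n) if mode == "feature" else np.full(n, 1.0 / n)
        return cls(v, mode)

    def normalised(self) -> "WeightVector":
        v = self.values
        scale = v.mean() if self.mode == "feature" else v.sum()
        return WeightVector(v / scale, self.mode)

    def validate(self, tol: float = 1e-6) -> None:
        if (self.values <= 0).any():
            raise ValueError("weights must be strictly positive")
        target = self.values.mean() if self.mode == "feature" else self.values.sum()
        if abs(target - 1.0) > tol:
            kind = "mean" if self.mode == "feature" else "sum"
            raise ValueError(f"weight {kind} is {target}, expected 1")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PathSegmentation:
    """Partition of an alignment path into template-index blocks."""

    boundaries: np.ndarray       # (n_segments + 1,) template indices
    step_slices: list[slice]     # step-index slice per segment
    path: AlignmentPath

    @property
    def n_segments(self) -> int:
        return len(self.step_slices)


# ---------------------------------------------------------------------------
# dynamic-programming kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dp_banded(x, y, w, lo, hi):
    """Weighted-L1 DTW restricted to the corridor lo[i] <= j < hi[i].

    Returns (distance, path array).  The corridor must contain (0, 0) and
    (N-1, M-1) and be row-wise contiguous and monotone, which the corridor
    builders guarantee.  Tie-break: diagonal, then template advance.
    """
    n, m = x.shape[0], y.shape[0]
    k = x.shape[1]
    INF = np.inf
    # dense accumulated-cost matrix; corridor cells only are filled
    acc = np.full((n, m), INF)
    for i in range(n):
        for j in range(lo[i], hi[i]):
            c = 0.0
            for d in range(k):
                c += w[d] * abs(x[i, d] - y[j, d])
            if i == 0 and j == 0:
                acc[0, 0] = c
                continue
            best = INF
            if i > 0 and j > 0 and acc[i - 1, j - 1] < best:
                best = acc[i - 1, j - 1]
            if i > 0 and acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if j > 0 and acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = c + best
    # backtrack, preferring diagonal then template advance
    length = 0
    i, j = n - 1, m - 1
    path = np.empty((n + m, 2), dtype=np.int64)
    while True:
        path[length, 0] = i
        path[length, 1] = j
        length += 1
        if i == 0 and j == 0:
            break
        pi, pj = i, j
        best = INF
        if i > 0 and j > 0 and acc[i - 1, j - 1] < best:
            best = acc[i - 1, j - 1]
            pi, pj = i - 1, j - 1
        if i > 0 and acc[i - 1, j] < best:
            best = acc[i - 1, j]
            pi, pj = i - 1, j
        if j > 0 and acc[i, j - 1] < best:
            best = acc[i, j - 1]
            pi, pj = i, j - 1
        i, j = pi, pj
    return acc[n - 1, m - 1], path[:length][::-1].copy()


def _dp_full(x, y, w):
    n, m = x.shape[0], y.shape[0]
    lo = np.zeros(n, dtype=np.int64)
    hi = np.full(n, m, dtype=np.int64)
    return _dp_banded(x, y, w, lo, hi)


def _halve(x):
    """Coarsen a series by averaging adjacent sample pairs."""
    n = x.shape[0] // 2
    out = 0.5 * (x[: 2 * n : 2] + x[1 : 2 * n : 2])
    if x.shape[0] % 2:  # keep the trailing sample
        out = np.vstack((out, x[-1:]))
    return out


def _corridor_from_path(path, n, m, radius):
    """Project a coarse path to the fine grid and inflate it by ``radius``.

    The coarse path visits every coarse row; per coarse row the spanned
    column range is inflated by ``radius`` in both axes (sliding min/max over
    rows, +-radius over columns), then each coarse cell (i, j) is projected
    onto fine rows 2i..2i+1 and columns 2j..2j+1.  Returns per-row contiguous
    column bounds (lo, hi) forming a monotone corridor.
    """
    nc = int(path[-1, 0]) + 1
    minj = np.empty(nc, dtype=np.int64)
    maxj = np.empty(nc, dtype=np.int64)
    minj.fill(m)
    maxj.fill(-1)
    np.minimum.at(minj, path[:, 0], path[:, 1])
    np.maximum.at(maxj, path[:, 0], path[:, 1])
    size = 2 * radius + 1
    minj = minimum_filter1d(minj, size, mode="nearest") - radius
    maxj = maximum_filter1d(maxj, size, mode="nearest") + radius
    ci = np.minimum(np.arange(n) // 2, nc - 1)
    lo = np.clip(2 * minj[ci], 0, m - 1)
    hi = np.clip(2 * maxj[ci] + 2, 1, m)
    # monotone non-decreasing bounds keep every corridor cell reachable
    lo = np.minimum(np.maximum.accumulate(lo), hi - 1)
    lo[0] = 0
    hi = np.maximum.accumulate(hi)
    hi[-1] = m
    return lo.astype(np.int64), hi.astype(np.int64)


def _fastdtw(x, y, radius, w):
    min_size = radius + 2
    if x.shape[0] <= min_size or y.shape[0] <= min_size:
        return _dp_full(x, y, w)
    _, coarse_path = _fastdtw(_halve(x), _halve(y), radius, w)
    lo, hi = _corridor_from_path(coarse_path, x.shape[0], y.shape[0], radius)
    return _dp_banded(x, y, w, lo, hi)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _check_pair(t: MovementSeries, a: MovementSeries):
    if t.channel_names != a.channel_names:
        raise ValueError(
            f"channel mismatch: {t.channel_names} vs {a.channel_names}"
        )


def dtw_arrays(x: np.ndarray, y: np.ndarray, radius: int = 10,
               weights: np.ndarray | None = None):
    """DTW between two (N, K) arrays; returns ``(distance, steps array)``."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] < 2 or y.shape[0] < 2:
        raise ValueError("series must have at least 2 samples")
    if x.shape[1] != y.shape[1]:
        raise ValueError("series must share the channel dimension")
    w = np.ones(x.shape[1]) if weights is None else np.asarray(weights, float)
    if w.shape[0] != x.shape[1]:
        raise ValueError("weight length must equal the number of channels")
    if radius >= max(x.shape[0], y.shape[0]):
        return _dp_full(x, y, w)
    return _fastdtw(x, y, int(radius), w)


def dtw(t: MovementSeries, a: MovementSeries, radius: int = 10):
    """Baseline L1 DTW distance and alignment path between template and movement."""
    _check_pair(t, a)
    dist, steps = dtw_arrays(t.samples, a.samples, radius=radius)
    return float(dist), AlignmentPath(steps, t.n_samples, a.n_samples)


def per_channel_errors(t: MovementSeries, a: MovementSeries,
                       path: AlignmentPath) -> np.ndarray:
    """Per-channel sums of |t - a| along a path; sums to the L1 DTW cost."""
    i0, i1 = path.steps[:, 0], path.steps[:, 1]
    return np.abs(t.samples[i0] - a.samples[i1]).sum(axis=0)


def dtw_feature(t: MovementSeries, a: MovementSeries, w: WeightVector,
                path_policy: str = "realign", radius: int = 10,
                check_weights: bool = True) -> float:
    """Feature-weighted DTW distance.

    Under ``realign`` the alignment path is re-optimised for the weighted
    cost; under ``reuse-baseline-path`` the unweighted path is kept and the
    weighted cost is accumulated along it (linear in w, used inside the
    weight optimiser).
    """
    _check_pair(t, a)
    if w.mode != "feature":
        raise ValueError("dtw_feature requires feature-mode weights")
    if len(w) != t.n_channels:
        raise ValueError(f"{len(w)} weights for {t.n_channels} channels")
    if check_weights:
        w.validate()
    elif (w.values <= 0).any():
        raise ValueError("weights must be strictly positive")
    if path_policy == "realign":
        dist, _ = dtw_arrays(t.samples, a.samples, radius=radius,
                             weights=w.values)
        return float(dist)
    if path_policy == "reuse-baseline-path":
        _, path = dtw(t, a, radius=radius)
        return float(per_channel_errors(t, a, path) @ w.values)
    raise ValueError(f"unknown path policy {path_policy!r}")


def segment_path(path: AlignmentPath, n_segments: int) -> PathSegmentation:
    """Partition a path into blocks of (near-)equal template-index spans.

    Template indices [0, N) are split into contiguous blocks; when N is not
    divisible the earliest blocks receive one extra index each.  Each path
    step belongs to the block containing its template index, so the
    partition is defined on the template axis only (asymmetric by design).
    """
    n = path.n_template
    if not 1 <= n_segments <= n:
        raise ValueError(f"n_segments must be in [1, {n}], got {n_segments}")
    base, rem = divmod(n, n_segments)
    sizes = np.full(n_segments, base, dtype=np.int64)
    sizes[:rem] += 1
    boundaries = np.concatenate(([0], np.cumsum(sizes)))
    i0 = path.steps[:, 0]
    # steps are sorted by template index; block edges via searchsorted
    cut = np.searchsorted(i0, boundaries[1:-1], side="left")
    edges = np.concatenate(([0], cut, [len(path)]))
    slices = [slice(int(edges[j]), int(edges[j + 1])) for j in range(n_segments)]
    return PathSegmentation(boundaries, slices, path)


def per_segment_errors(t: MovementSeries, a: MovementSeries,
                       path: AlignmentPath, n_segments: int) -> np.ndarray:
    """Partial DTW contributions per template segment; sums to the total."""
    seg = segment_path(path, n_segments)
    i0, i1 = path.steps[:, 0], path.steps[:, 1]
    step_cost = np.abs(t.samples[i0] - a.samples[i1]).sum(axis=1)
    return np.array([step_cost[s].sum() for s in seg.step_slices])


def dtw_segment(t: MovementSeries, a: MovementSeries, w: WeightVector,
                radius: int = 10, check_weights: bool = True) -> float:
    """Segment-weighted DTW: baseline path first, then weighted block sums."""
    _check_pair(t, a)
    if w.mode != "segment":
        raise ValueError("dtw_segment requires segment-mode weights")
    if check_weights:
        w.validate()
    _, path = dtw(t, a, radius=radius)
    contrib = per_segment_errors(t, a, path, len(w))
    return float(contrib @ w.values)
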