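"""Independent brute-force oracles used only by the tests.

These are deliberately written in plain Python, separately from the package
implementation, so that agreement between the two is meaningful.
"""

import math

import numpy as np


def dtw_dp_oracle(x, y, w=None):
    """Full O(NM) dynamic-programming DTW with L1 cost.

    Tie-break on backtracking: diagonal first, then the step advancing the
    first (template) index.  Returns ``(distance, path list)``.
    """
    x = np.atleast_2d(np.asarray(x, float).T).T
    y = np.atleast_2d(np.asarray(y, float).T).T
    n, m = len(x), len(y)
    k = x.shape[1]
    if w is None:
        w = [1.0] * k
    cost = [[sum(w[d] * abs(x[i][d] - y[j][d]) for d in range(k))
             for j in range(m)] for i in range(n)]
    acc = [[math.inf] * m for _ in range(n)]
    acc[0][0] = cost[0][0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = math.inf
            if i > 0 and j > 0:
                best = min(best, acc[i - 1][j - 1])
            if i > 0:
                best = min(best, acc[i - 1][j])
            if j > 0:
                best = min(best, acc[i][j - 1])
            acc[i][j] = cost[i][j] + best
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        cands = []
        if i > 0 and j > 0:
            cands.append((acc[i - 1][j - 1], 0, (i - 1, j - 1)))
        if i > 0:
            cands.append((acc[i - 1][j], 1, (i - 1, j)))
        if j > 0:
            cands.append((acc[i][j - 1], 2, (i, j - 1)))
        _, _, (i, j) = min(cands)
        path.append((i, j))
    return acc[n - 1][m - 1], path[::-1]


def icc_mean_squares_oracle(x):
    """Two-way ANOVA mean squares -> absolute-agreement ICCs, coded plainly."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((x - grand) ** 2).sum()
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    a1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    ak = (msr - mse) / (msr + (msc - mse) / n)
    return a1, ak
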