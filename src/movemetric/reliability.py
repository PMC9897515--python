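"""Inter- and intra-rater agreement via intraclass correlation coefficients.

Ratings of n pairs by k raters form a complete two-way layout (rows =
pairs, columns = raters).  Agreement is quantified with the two-way
mixed-effects, absolute-agreement ICC — ICC(A,1) for a single rating and
ICC(A,k) for the k-rater mean — computed from the ANOVA mean squares
(McGraw & Wong conventions; for absolute agreement the mixed- and
random-effects estimators coincide):

    MSR = between-pair mean square, MSC = between-rater mean square,
    MSE = residual mean square,

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n)

with exact F-based 95% confidence intervals (Satterthwaite degrees of
freedom for the absolute-agreement forms) and the between-pair F test
F = MSR/MSE on (n-1, (n-1)(k-1)) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import RatingRecord


@dataclass
class RatingMatrix:
    """Complete n_pairs x n_raters rating layout."""

    values: np.ndarray
    pair_ids: list[str]
    rater_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 pairs and 2 raters")
        if not np.isfinite(self.values).all():
            raise ValueError("rating matrix has missing or non-finite cells"
                             " (no imputation is performed)")
        if len(self.pair_ids) != n or len(self.rater_ids) != k:
            raise ValueError("id lists must match the matrix shape")

    @classmethod
    def from_records(cls, records: list[RatingRecord]) -> "RatingMatrix":
        df = pd.DataFrame(
            [(r.pair_id, r.rater_id, r.rating) for r in records],
            columns=["pair_id", "rater_id", "rating"],
        ).pivot(index="pair_id", columns="rater_id", values="rating")
        if df.isna().any().any():
            raise ValueError("incomplete rating design: every rater must "
                             "rate every pair")
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    F: float
    df1: int
    df2: int
    p_value: float
    form: str


def _mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(m: RatingMatrix, form: str = "single", alpha: float = 0.05) -> ICCResult:
    """Absolute-agreement ICC: ICC(A,1) (``single``) or ICC(A,k) (``mean``)."""
    if form not in ("single", "mean"):
        raise ValueError(f"form must be 'single' or 'mean', got {form!r}")
    x = m.values
    n, k = x.shape
    msr, msc, mse = _mean_squares(x)
    if msr < 1e-300:
        warnings.warn("zero between-pair variance; ICC set to 0")
        return ICCResult(0.0, float("nan"), float("nan"), float("nan"),
                         n - 1, (n - 1) * (k - 1), float("nan"), form)

    est1 = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # F test of between-pair variance
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse < 1e-300:  # perfect within-pair agreement
        f_stat, p = float("inf"), 0.0
        lo1 = hi1 = 1.0
    else:
        f_stat = msr / mse
        p = float(stats.f.sf(f_stat, df1, df2))
        # Satterthwaite df for the absolute-agreement interval
        a = (k * est1) / (n * (1.0 - est1)) if est1 < 1.0 else float("inf")
        b = 1.0 + (k * est1 * (n - 1)) / (n * (1.0 - est1)) if est1 < 1.0 else float("inf")
        if np.isfinite(a) and np.isfinite(b):
            num = (a * msc + b * mse) ** 2
            den = ((a * msc) ** 2 / (k - 1)
                   + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            v = num / den
            f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
            f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
            lo1 = (n * (msr - f_l * mse)
                   / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi1 = (n * (f_u * msr - mse)
                   / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
        else:
            lo1 = hi1 = 1.0

    if form == "single":
        est, lo, hi = est1, lo1, hi1
    else:
        sb = lambda r: k * r / (1.0 + (k - 1) * r)  # Spearman-Brown step-up
        est, lo, hi = sb(est1), sb(lo1), sb(hi1)
    est = min(float(est), 1.0)  # guard rounding above the theoretical maximum
    return ICCResult(est, float(lo), float(hi), float(f_stat),
                     df1, df2, p, form)


def pair_disagreement(m: RatingMatrix) -> np.ndarray:
    """Per-pair disagreement: sample SD of the raters' ratings of that pair."""
    return m.values.std(axis=1, ddof=1)


def compare_reliability(a: RatingMatrix, b: RatingMatrix):
    """Welch t-test comparing per-pair rater agreement of two designs.

    The per-pair disagreement score is the SD across raters; the statistic
    is positive when design ``a`` shows better agreement (smaller
    disagreement) than ``b``.  This is a reconstruction of an agreement
    comparison from summary scores, not an ICC-difference test.
    """
    if a.n_pairs < 3 or b.n_pairs < 3:
        raise ValueError("need at least 3 pairs in each design")
    da, db = pair_disagreement(a), pair_disagreement(b)
    res = stats.ttest_ind(db, da, equal_var=False)
    # Welch-Satterthwaite df
    va, vb = da.var(ddof=1) / len(da), db.var(ddof=1) / len(db)
    if va + vb > 0:
        df = (va + vb) ** 2 / (va ** 2 / (len(da) - 1) + vb ** 2 / (len(db) - 1))
    else:
        df = len(da) + len(db) - 2
    return float(res.statistic), float(df), float(res.pvalue)
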