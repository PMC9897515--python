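"""Motor-learning rates from alignment errors over practice time.

Each performance is aligned once to the template with the all-channel
baseline DTW; the L1 cost decomposes exactly into per-channel sums (and,
via the template-axis segmentation, into per-segment sums).  Averaging
those errors over participants at each practice rank gives one error curve
per channel or segment, to which a three-parameter exponential

    y(x) = a * exp(b * x) + c,   a >= 0

is fitted by nonlinear least squares.  The rate coefficient is b: more
negative means faster improvement (error decays faster with practice).
Correlating fitted weights with rate coefficients asks whether the units
that raters implicitly emphasised are also the units where most learning
happened; a negative correlation says yes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .dtw import WeightVector, dtw, per_channel_errors, per_segment_errors
from .io import MovementSeries


@dataclass
class ExpFit:
    a: float
    b: float
    c: float
    rmse: float
    fallback: bool = False


@dataclass
class LearningCurve:
    """Error-versus-practice curve for one channel or segment."""

    unit: str
    x: np.ndarray
    y: np.ndarray
    fit: ExpFit

    @property
    def rate_coefficient(self) -> float:
        return self.fit.b


def _movement_index(movements: list[MovementSeries]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(
        [m.key() for m in movements],
        names=["participant_id", "session_id", "trial_id"])


def per_feature_errors(template: MovementSeries,
                       movements: list[MovementSeries],
                       radius: int = 10) -> pd.DataFrame:
    """Per-channel alignment error of each movement (all-channel baseline path).

    Rows are indexed by (participant, session, trial); row sums equal the
    total DTW distance of that movement to the template.
    """
    rows = []
    for m in movements:
        _, path = dtw(template, m, radius=radius)
        rows.append(per_channel_errors(template, m, path))
    return pd.DataFrame(rows, index=_movement_index(movements),
                        columns=list(template.channel_names))


def per_segment_errors_table(template: MovementSeries,
                             movements: list[MovementSeries],
                             n_segments: int, radius: int = 10) -> pd.DataFrame:
    """Per-segment partial DTW contributions of each movement."""
    rows = []
    for m in movements:
        _, path = dtw(template, m, radius=radius)
        rows.append(per_segment_errors(template, m, path, n_segments))
    return pd.DataFrame(rows, index=_movement_index(movements),
                        columns=[f"segment_{j}" for j in range(n_segments)])


def fit_exponential(x, y) -> ExpFit:
    """Least-squares fit of y = a*exp(b*x) + c with a >= 0 and c >= 0.

    The fitted quantities are alignment errors, which cannot fall below
    zero, so the asymptotic floor is constrained nonnegative; without this
    the floor and the rate trade off freely on weakly curved data and the
    rate estimate becomes erratic.  Initial values come from a log-linear
    regression on the floored data; if the nonlinear fit fails to converge,
    that log-linear solution is returned with ``fallback=True``.  A flat
    series yields b ~ 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 4:
        raise ValueError("need at least 4 points to fit an exponential")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in curve data")
    span = float(np.ptp(y))
    if span < 1e-12:  # no change over practice: degenerate flat fit
        return ExpFit(0.0, 0.0, float(y.mean()), 0.0, fallback=False)

    # log-linear initialisation on y shifted above its floor
    eps = 1e-3 * span
    z = np.log(y - y.min() + eps)
    b0, log_a0 = np.polyfit(x, z, 1)
    init = (float(np.exp(log_a0)), float(min(b0, -1e-6)),
            float(max(y.min(), 0.0)))
    fallback_fit = ExpFit(init[0], init[1], init[2],
                          _rmse(y, _expm(x, *init)), fallback=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _expm, x, y, p0=init,
                bounds=([0.0, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000)
    except RuntimeError:
        warnings.warn("exponential fit did not converge; using log-linear "
                      "fallback")
        return fallback_fit
    fit = ExpFit(float(popt[0]), float(popt[1]), float(popt[2]),
                 _rmse(y, _expm(x, *popt)))
    return fit if fit.rmse <= fallback_fit.rmse + 1e-12 else fallback_fit


def _expm(x, a, b, c):
    return a * np.exp(b * x) + c


def _rmse(y, yhat) -> float:
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def learning_curves(errors: pd.DataFrame) -> list[LearningCurve]:
    """Fit one exponential per column of a practice-ordered error table.

    Errors are first averaged over participants at each (session, trial)
    practice rank, giving one mean error per practice index; curves are then
    fitted on those averaged values.
    """
    mean_by_rank = errors.groupby(level=["session_id", "trial_id"]).mean()
    mean_by_rank = mean_by_rank.sort_index()
    x = np.arange(len(mean_by_rank), dtype=np.float64)
    out = []
    for col in mean_by_rank.columns:
        y = mean_by_rank[col].to_numpy()
        out.append(LearningCurve(unit=str(col), x=x, y=y,
                                 fit=fit_exponential(x, y)))
    return out


def weights_vs_rates(weights: WeightVector, curves: list[LearningCurve]):
    """Pearson correlation between weights and rate coefficients.

    Returns ``(r, df, p)`` with df = n_units - 2 (the r(n) convention counts
    units, df is reported for the test).  A negative r means highly weighted
    units improved fastest.
    """
    if len(weights) != len(curves):
        raise ValueError(
            f"{len(weights)} weights for {len(curves)} learning curves")
    b = np.array([c.rate_coefficient for c in curves])
    r, p = pearsonr(weights.values, b)
    return float(r), len(curves) - 2, float(p)
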