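"""Logistic growth fitting and clonal fitness metrics.

Single-clone confluence or fluorescence-area trajectories are summarised by a
three-parameter logistic model

    x(t) = K / (1 + ((K - x0) / x0) * exp(-r t))

whose intrinsic growth rate ``r`` (1/h) is used as an absolute fitness measure
of the clone; the doubling time is ``ln 2 / r``.  Groups of clones (for example
drug-sensitive versus efflux-pump-expressing resistant clones) are compared by
a pooled-variance two-sample t-test on the fitted rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "logistic",
    "LogisticGrowthModel",
    "FitnessComparison",
    "CorrelationResult",
    "fit_logistic",
    "fit_curves",
    "time_to_threshold",
    "compare_fitness",
    "correlate",
]

MIN_POINTS = 5


def logistic(t, r, K, x0):
    """Closed-form logistic trajectory x(t) = K / (1 + ((K-x0)/x0) e^{-rt})."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - x0) / x0) * np.exp(-r * t))


class LogisticGrowthModel(BaseEstimator, RegressorMixin):
    """Least-squares logistic growth fit.

    Parameters
    ----------
    r_max : float
        Upper bound on the intrinsic growth rate (1/h).  The biological range
        for adherent tumour lines is well below 1/h (a 42 min doubling time).
    k_expand : float
        Upper bound on carrying capacity as a multiple of the largest observed
        signal; accommodates curves that have not plateaued.

    Attributes
    ----------
    r_ : float
        Intrinsic growth rate (1/h).
    K_ : float
        Carrying capacity (signal units).
    x0_ : float
        Fitted initial signal.
    t_d_ : float
        Doubling time ln(2)/r_ (h).
    rss_ : float
        Residual sum of squares.
    converged_ : bool
        False when the optimiser failed or a parameter sits on a bound.
    """

    def __init__(self, r_max: float = 1.0, k_expand: float = 10.0):
        self.r_max = r_max
        self.k_expand = k_expand

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.size != y.size:
            raise ValueError("t and y must have equal length")
        if t.size < MIN_POINTS:
            raise ValueError(
                f"logistic fit needs >= {MIN_POINTS} time points, got {t.size}"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in growth curve")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(y) == 0:
            raise ValueError("flat curve: all signal values equal; cannot fit growth")
        if np.any(y < 0):
            raise ValueError("negative signal values")

        ymax = float(np.max(y))
        first_pos = float(y[y > 0][0]) if np.any(y > 0) else ymax / 100.0
        k0 = 1.05 * ymax
        x00 = min(first_pos, 0.999 * k0)
        r0 = self._slope_init(t, y, k0, x00)

        lower = [1e-8, ymax / 2.0, 1e-12]
        upper = [self.r_max, self.k_expand * ymax, max(first_pos * 3.0, 1e-9)]
        p0 = [
            np.clip(r0, lower[0] * 2, upper[0] * 0.9),
            np.clip(k0, lower[1] * 1.001, upper[1] * 0.999),
            np.clip(x00, lower[2] * 2, upper[2] * 0.999),
        ]
        try:
            popt, _ = optimize.curve_fit(
                logistic,
                t,
                y,
                p0=p0,
                bounds=(lower, upper),
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            ok = True
        except RuntimeError:
            popt, ok = np.asarray(p0), False

        self.r_, self.K_, self.x0_ = (float(v) for v in popt)
        resid = y - logistic(t, *popt)
        self.rss_ = float(resid @ resid)
        self.t_d_ = float(np.log(2) / self.r_)
        self.converged_ = bool(ok and not self._on_bounds(popt, lower, upper))
        self.n_points_ = int(t.size)
        return self

    @staticmethod
    def _slope_init(t, y, K, x0):
        # slope of log(x/(K-x)) over the first half of the series is r
        half = max(MIN_POINTS, t.size // 2)
        tt, yy = t[:half], np.clip(y[:half], 1e-12, K * (1 - 1e-9))
        z = np.log(yy / (K - yy))
        slope = np.polyfit(tt, z, 1)[0]
        return slope if slope > 0 else 0.02

    @staticmethod
    def _on_bounds(p, lower, upper, rtol=1e-6):
        p, lower, upper = map(np.asarray, (p, lower, upper))
        span = upper - lower
        return bool(np.any(p - lower < rtol * span) or np.any(upper - p < rtol * span))

    def predict(self, t):
        check_is_fitted(self, "r_")
        return logistic(np.asarray(t, dtype=float).ravel(), self.r_, self.K_, self.x0_)

    def time_to_threshold(self, threshold: float) -> float:
        """Analytic time at which the fitted curve crosses ``threshold``."""
        check_is_fitted(self, "r_")
        return time_to_threshold(self.r_, self.K_, self.x0_, threshold)


def fit_logistic(times, values) -> LogisticGrowthModel:
    """Fit the logistic growth model to one trajectory (thin wrapper)."""
    return LogisticGrowthModel().fit(times, values)


def time_to_threshold(r: float, K: float, x0: float, threshold: float) -> float:
    """Hours for the logistic curve to reach ``threshold`` signal units.

    t = ln( ((K-x0)/x0) / ((K-th)/th) ) / r, defined for x0 <= threshold < K.
    """
    if not (x0 <= threshold < K):
        raise ValueError(
            f"threshold {threshold} outside fitted range (x0={x0}, K={K})"
        )
    if threshold == x0:
        return 0.0
    return float(np.log(((K - x0) / x0) / ((K - threshold) / threshold)) / r)


def fit_curves(
    curves: pd.DataFrame,
    threshold: float | None = None,
    raw_interpolation: bool = False,
) -> pd.DataFrame:
    """Fit every (clone, replicate, channel) trajectory in a long-format table.

    Each replicate is fitted independently; per-clone summaries are means over
    replicates.  Returns one row per trajectory with columns
    ``clone, replicate, channel, r, K, x0, t_d, rss, converged`` plus ``t50``
    when ``threshold`` is given (from the fitted model by default, or by linear
    interpolation of the raw curve with ``raw_interpolation=True``).
    """
    rows = []
    for (clone, rep, channel), grp in curves.groupby(
        ["clone", "replicate", "channel"], sort=True
    ):
        grp = grp.sort_values("time_h")
        model = fit_logistic(grp["time_h"].to_numpy(), grp["value"].to_numpy())
        row = {
            "clone": clone,
            "replicate": rep,
            "channel": channel,
            "r": model.r_,
            "K": model.K_,
            "x0": model.x0_,
            "t_d": model.t_d_,
            "rss": model.rss_,
            "converged": model.converged_,
        }
        if threshold is not None:
            if raw_interpolation:
                row["t50"] = _interp_crossing(
                    grp["time_h"].to_numpy(), grp["value"].to_numpy(), threshold
                )
            else:
                try:
                    row["t50"] = model.time_to_threshold(threshold)
                except ValueError:
                    row["t50"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _interp_crossing(t, y, threshold):
    above = np.nonzero(y >= threshold)[0]
    if above.size == 0 or above[0] == 0:
        return np.nan if above.size == 0 else float(t[0])
    i = above[0]
    frac = (threshold - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


@dataclass
class FitnessComparison:
    """Pooled-variance two-sample t comparison of group growth rates."""

    mean_a: float
    mean_b: float
    ratio: float
    t_stat: float
    df: int
    p_value: float
    infinite_t: bool = False


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def compare_fitness(group_a, group_b) -> FitnessComparison:
    """Compare mean intrinsic growth rates of two clone groups.

    Student t with pooled variance (df = n_a + n_b - 2); the reported ratio is
    mean(group_a)/mean(group_b).  A zero pooled variance with unequal means is
    reported as an infinite t with a flag rather than an exception.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    df = int(a.size + b.size - 2)
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0.0:
        if a.mean() == b.mean():
            return FitnessComparison(a.mean(), b.mean(), 1.0, 0.0, df, 1.0)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return FitnessComparison(
            a.mean(), b.mean(), a.mean() / b.mean(), t, df, 0.0, infinite_t=True
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return FitnessComparison(
        float(a.mean()), float(b.mean()), float(a.mean() / b.mean()),
        float(t), df, float(p),
    )


def correlate(x, y) -> CorrelationResult:
    """Ordinary least squares of y on x, reporting slope, intercept and R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return CorrelationResult(
        float(res.slope), float(res.intercept), float(res.rvalue**2), int(x.size)
    )
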