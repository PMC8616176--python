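"""Dose-response fitting: 4PL/IC50, growth-rate-corrected GR metrics, mixtures.

Two complementary summaries of a viability dose curve are provided:

* the four-parameter logistic (4PL) fit of relative viability, with the IC50
  reported in the *absolute* convention (dose where viability crosses 50% of
  the vehicle control) alongside the curve midpoint ``ec50_rel``;
* the normalized growth-rate inhibition value

      GR(c) = 2^( log2(x_c/x0) / log2(x_ctrl/x0) ) - 1

  which rescales the drug effect to a per-division basis, removing the
  division-rate confound that inflates IC50s of slow-growing clones.  The
  GR50 is the concentration where the fitted GR curve crosses 0.5; dose
  curves that stay flat near GR = 1 or never cross 0.5 within the tested
  range are flagged UTBD ("unable to be determined").

Mixture predictions assume independent action: a population with resistant
fraction ``f`` survives ``(1-f) S_neg(d) + f S_pos(d)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FourPLModel",
    "GRCurveModel",
    "MixturePrediction",
    "fit_4pl",
    "fold_resistance",
    "compute_gr",
    "fit_gr_curve",
    "gr_table",
    "predict_mixture_ic50",
    "compare_group_ic50",
]


def _four_pl(d, ec50, hill, top, bottom):
    d = np.asarray(d, dtype=float)
    return bottom + (top - bottom) / (1.0 + (d / ec50) ** hill)


class FourPLModel(BaseEstimator, RegressorMixin):
    """Least-squares 4PL fit of viability fraction versus dose.

    Viability is expected on the control-normalised scale (control = 1).

    Attributes
    ----------
    ec50_rel_ : float
        Curve midpoint (dose of half-maximal effect between top and bottom).
    ic50_abs_ : float or nan
        Dose where the fitted curve crosses 0.5 (absolute convention);
        nan with ``ic50_defined_ = False`` when the curve never reaches 0.5.
    hill_, top_, bottom_, rss_, converged_
    """

    def __init__(self, ic50_level: float = 0.5):
        self.ic50_level = ic50_level

    def fit(self, dose, viability):
        d = np.asarray(dose, dtype=float).ravel()
        v = np.asarray(viability, dtype=float).ravel()
        if d.size != v.size:
            raise ValueError("dose and viability must have equal length")
        if np.unique(d).size < 4:
            raise ValueError("4PL fit needs >= 4 distinct doses")
        if np.any(d <= 0):
            raise ValueError("doses must be positive")

        order = np.argsort(d)
        ds, vs = d[order], v[order]
        top0 = float(np.clip(vs[:max(1, d.size // 4)].mean(), 0.5, 2.0))
        bot0 = float(np.clip(vs[-max(1, d.size // 4):].mean(), 0.0, top0 - 1e-3))
        mid = 0.5 * (top0 + bot0)
        ec0 = float(ds[np.argmin(np.abs(vs - mid))])
        p0 = [max(ec0, ds[0]), 1.0, top0, bot0]
        lower = [ds[0] / 1e4, 0.05, 0.0, -0.5]
        upper = [ds[-1] * 1e4, 20.0, 3.0, 1.5]
        try:
            popt, _ = optimize.curve_fit(
                _four_pl, d, v, p0=p0, bounds=(lower, upper),
                maxfev=20000, xtol=1e-13, ftol=1e-13,
            )
            ok = True
        except RuntimeError:
            popt, ok = np.asarray(p0), False
        self.ec50_rel_, self.hill_, self.top_, self.bottom_ = map(float, popt)
        resid = v - _four_pl(d, *popt)
        self.rss_ = float(resid @ resid)
        # a fit that says viability rises with dose is not a dose response
        increasing = self.top_ < self.bottom_
        self.converged_ = bool(ok and not increasing)
        self.ic50_abs_ = self._solve_level(self.ic50_level)
        self.ic50_defined_ = bool(np.isfinite(self.ic50_abs_))
        return self

    def _solve_level(self, level: float) -> float:
        top, bot, h, e = self.top_, self.bottom_, self.hill_, self.ec50_rel_
        if not (min(top, bot) < level < max(top, bot)):
            return float("nan")
        return float(e * ((top - bot) / (level - bot) - 1.0) ** (1.0 / h))

    def predict(self, dose):
        check_is_fitted(self, "ec50_rel_")
        return _four_pl(np.asarray(dose, dtype=float).ravel(),
                        self.ec50_rel_, self.hill_, self.top_, self.bottom_)


def fit_4pl(dose, viability) -> FourPLModel:
    """Fit a 4PL viability curve (thin wrapper)."""
    return FourPLModel().fit(dose, viability)


def fold_resistance(group_pos, group_neg, decimals: int | None = 1):
    """Fold-resistance: ratio of arithmetic mean IC50s (resistant/sensitive).

    Undefined (nan) IC50s are excluded; the result is rounded to ``decimals``
    places (``None`` for full precision).
    """
    pos = np.asarray(group_pos, dtype=float)
    neg = np.asarray(group_neg, dtype=float)
    pos, neg = pos[np.isfinite(pos)], neg[np.isfinite(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups need at least one defined IC50")
    if np.any(pos <= 0) or np.any(neg <= 0):
        raise ValueError("IC50 values must be positive")
    fold = float(pos.mean() / neg.mean())
    return round(fold, decimals) if decimals is not None else fold


def compute_gr(x_c, x0, x_ctrl):
    """Normalized growth-rate inhibition of one (treated, t0, control) triple.

    GR = 2^( log2(x_c/x0) / log2(x_ctrl/x0) ) - 1.  Accepts arrays for x_c.
    """
    x_c = np.asarray(x_c, dtype=float)
    if x0 <= 0:
        raise ValueError("time-zero count must be positive")
    if x_ctrl <= x0:
        raise ValueError("GR undefined: control did not grow (x_ctrl <= x0)")
    if np.any(x_c <= 0):
        raise ValueError("treated counts must be positive")
    gr = 2.0 ** (np.log2(x_c / x0) / np.log2(x_ctrl / x0)) - 1.0
    return float(gr) if gr.ndim == 0 else gr


def _gr_curve(c, gr_inf, gec50, h):
    c = np.asarray(c, dtype=float)
    return gr_inf + (1.0 - gr_inf) / (1.0 + (c / gec50) ** h)


class GRCurveModel(BaseEstimator, RegressorMixin):
    """Sigmoidal fit of per-dose GR values; GR50 with UTBD flagging.

    GR(c) = gr_inf + (1 - gr_inf) / (1 + (c/gec50)^h).  The GR50 is solved
    analytically from GR(c) = 0.5.  ``utbd_`` is set (and ``gr50_`` is nan)
    when the fitted curve is flat near 1 over the tested range
    (|1 - GR| < ``flat_tol`` everywhere) or never crosses 0.5 in range.
    """

    def __init__(self, flat_tol: float = 0.1):
        self.flat_tol = flat_tol

    def fit(self, dose, gr):
        c = np.asarray(dose, dtype=float).ravel()
        g = np.asarray(gr, dtype=float).ravel()
        if c.size != g.size:
            raise ValueError("dose and gr must have equal length")
        if np.unique(c).size < 4:
            raise ValueError("GR curve fit needs >= 4 distinct doses")
        if np.any(c <= 0):
            raise ValueError("doses must be positive")
        gmin = float(np.min(g))
        p0 = [np.clip(gmin, -0.99, 0.9), float(np.median(c)), 1.0]
        lower = [-1.0, np.min(c) / 1e4, 0.05]
        upper = [1.0, np.max(c) * 1e4, 20.0]
        try:
            popt, _ = optimize.curve_fit(
                _gr_curve, c, g, p0=p0, bounds=(lower, upper),
                maxfev=20000, xtol=1e-13, ftol=1e-13,
            )
            ok = True
        except RuntimeError:
            popt, ok = np.asarray(p0), False
        self.gr_inf_, self.gec50_, self.h_gr_ = map(float, popt)
        resid = g - _gr_curve(c, *popt)
        self.rss_ = float(resid @ resid)
        self.converged_ = bool(ok)
        self.dose_range_ = (float(np.min(c)), float(np.max(c)))
        self.gr50_, self.utbd_ = self._solve_gr50()
        return self

    def _solve_gr50(self):
        lo, hi = self.dose_range_
        fitted = _gr_curve(np.array([lo, hi]), self.gr_inf_, self.gec50_, self.h_gr_)
        if np.all(np.abs(1.0 - _gr_curve(
                np.geomspace(lo, hi, 50), self.gr_inf_, self.gec50_, self.h_gr_))
                < self.flat_tol):
            return float("nan"), True  # flat GR dose curve
        if self.gr_inf_ >= 0.5:
            return float("nan"), True  # effect never reaches GR = 0.5
        gr50 = self.gec50_ * ((1.0 - self.gr_inf_) / (0.5 - self.gr_inf_)
                              - 1.0) ** (1.0 / self.h_gr_)
        if not (lo <= gr50 <= hi):
            return float("nan"), True  # no crossing within the tested range
        return float(gr50), False

    def predict(self, dose):
        check_is_fitted(self, "gec50_")
        return _gr_curve(np.asarray(dose, dtype=float).ravel(),
                         self.gr_inf_, self.gec50_, self.h_gr_)


def fit_gr_curve(dose, gr, flat_tol: float = 0.1) -> GRCurveModel:
    """Fit the GR dose curve (thin wrapper)."""
    return GRCurveModel(flat_tol=flat_tol).fit(dose, gr)


def gr_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-dose GR values from a counts table with roles.

    Expects columns ``sample, replicate, role, dose_uM, count`` with roles
    ``treated``/``control``/``time0`` (the synthetic generator dialect).
    Counts are averaged over replicates per dose before applying the GR
    formula with the replicate-mean control and time-zero counts.
    """
    out = []
    for sample, grp in counts.groupby("sample"):
        x0 = grp.loc[grp["role"] == "time0", "count"].mean()
        ctrl = grp.loc[grp["role"] == "control", "count"].mean()
        treated = (grp[grp["role"] == "treated"]
                   .groupby("dose_uM")["count"].mean())
        gr = compute_gr(treated.to_numpy(), x0, ctrl)
        out.append(pd.DataFrame({"sample": sample,
                                 "dose_uM": treated.index.to_numpy(),
                                 "gr": gr}))
    return pd.concat(out, ignore_index=True)


@dataclass
class MixturePrediction:
    fraction_positive: float
    ic50: float
    defined: bool
    doses: np.ndarray
    survival: np.ndarray


def predict_mixture_ic50(fit_neg: FourPLModel, fit_pos: FourPLModel,
                         f: float, doses=None) -> MixturePrediction:
    """Independent-action mixture IC50 by bisection of the blended curve.

    S(d) = (1-f) S_neg(d) + f S_pos(d); the IC50 solves S(d) = 0.5 over the
    bracket [min dose / 100, max dose * 100] built from both fits' ranges.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("fraction f must lie in [0, 1]")
    for m in (fit_neg, fit_pos):
        check_is_fitted(m, "ec50_rel_")
        if not m.converged_:
            raise ValueError("both 4PL fits must have converged")

    def blend(d):
        return (1.0 - f) * fit_neg.predict(d) + f * fit_pos.predict(d)

    if doses is None:
        lo = min(fit_neg.ec50_rel_, fit_pos.ec50_rel_) / 100.0
        hi = max(fit_neg.ec50_rel_, fit_pos.ec50_rel_) * 100.0
    else:
        doses = np.asarray(doses, dtype=float)
        lo, hi = float(np.min(doses)) / 100.0, float(np.max(doses)) * 100.0
    grid = np.geomspace(lo, hi, 400)
    surv = blend(grid)

    f_lo = float(blend([lo])[0]) - 0.5
    f_hi = float(blend([hi])[0]) - 0.5
    if f_lo * f_hi > 0:
        return MixturePrediction(f, float("nan"), False, grid, surv)
    ic50 = optimize.brentq(lambda d: float(blend([d])[0]) - 0.5, lo, hi,
                           xtol=1e-12, rtol=1e-15)
    return MixturePrediction(f, float(ic50), True, grid, surv)


def compare_group_ic50(replicate_ic50s: dict, ref_negative: str,
                       ref_positive: str, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Student t-tests of each condition against the pure clones.

    ``replicate_ic50s`` maps condition labels (pure clones and mixtures) to
    lists of replicate IC50s (>= 3 each).  Each non-reference condition is
    compared two-sided against ``ref_negative`` and ``ref_positive``;
    comparisons with p >= ``alpha`` are marked NS.
    """
    for label, vals in replicate_ic50s.items():
        if len(vals) < 3:
            raise ValueError(f"condition {label!r} needs >= 3 replicates")
    neg = np.asarray(replicate_ic50s[ref_negative], dtype=float)
    pos = np.asarray(replicate_ic50s[ref_positive], dtype=float)
    rows = []
    for label, vals in replicate_ic50s.items():
        v = np.asarray(vals, dtype=float)
        row = {"condition": label, "mean_ic50": float(v.mean()),
               "sem": float(v.std(ddof=1) / np.sqrt(v.size))}
        for ref_label, ref in (("vs_negative", neg), ("vs_positive", pos)):
            if np.array_equal(v, ref):
                p = 1.0  # identical replicate sets (includes self-comparison)
            else:
                _, p = stats.ttest_ind(v, ref, equal_var=True)
            row[f"p_{ref_label}"] = float(p)
            row[f"ns_{ref_label}"] = bool(p >= alpha)
        rows.append(row)
    return pd.DataFrame(rows)
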