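"""Two-clone Lotka-Volterra competition: simulation, fitting, bootstrap.

The model couples a drug-sensitive clone ``s`` and a resistant clone ``r``:

    dx_s/dt = r_s x_s (1 - (x_s + alpha_sr x_r) / K_s)
    dx_r/dt = r_r x_r (1 - (x_r + alpha_rs x_s) / K_r)

``alpha_sr`` is the per-capita crowding effect of the resistant clone on the
sensitive one and ``alpha_rs`` the reverse; their ratio ``alpha_rs/alpha_sr``
measures the asymmetry of competition (values above 1 mean the sensitive clone
suppresses the resistant clone more strongly than vice versa).

Fitting proceeds in stages.  Per-clone (r, K) are first estimated from
monoculture logistic fits; the two competition coefficients (plus a total
inoculum per co-culture, split by the known seeding fractions) are then
estimated by least squares on all co-culture channels jointly; finally all
parameters are refined together on monoculture and co-culture curves at once.
The joint refinement matters: the co-culture trajectories are so sensitive to
the growth rates that sub-percent errors in plugged-in monoculture estimates
would otherwise swamp the competition coefficients.  Residuals are taken on
the log scale, matching the multiplicative measurement noise of confluence
and fluorescence-area readouts (and making the fit invariant to rescaling the
signal units).  Uncertainty comes from a residual-resampling bootstrap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .growth import fit_logistic, logistic

__all__ = [
    "LVParams",
    "simulate_lv",
    "LotkaVolterraCompetition",
    "fit_lv",
    "bootstrap_lv",
]

DEFAULT_CHANNEL_MAP = {"yellow": "s", "red": "r"}
_CO_LABEL = re.compile(r"co[_ ]?(\d+)[_: ](\d+)$")


@dataclass
class LVParams:
    r_s: float
    r_r: float
    K_s: float
    K_r: float
    alpha_sr: float
    alpha_rs: float

    def __post_init__(self):
        if min(self.r_s, self.r_r, self.K_s, self.K_r) <= 0:
            raise ValueError(f"rates and capacities must be positive: {self}")
        if min(self.alpha_sr, self.alpha_rs) < 0:
            raise ValueError(f"competition coefficients must be >= 0: {self}")

    @property
    def ratio(self) -> float:
        return self.alpha_rs / self.alpha_sr


def _lv_rhs_stacked(t, y, r_s, r_r, K_s, K_r, a_sr, a_rs):
    # y stacks n independent (x_s, x_r) pairs: [s0, r0, s1, r1, ...]
    xs, xr = y[0::2], y[1::2]
    dxs = r_s * xs * (1.0 - (xs + a_sr * xr) / K_s)
    dxr = r_r * xr * (1.0 - (xr + a_rs * xs) / K_r)
    out = np.empty_like(y)
    out[0::2], out[1::2] = dxs, dxr
    return out


def _integrate(params: LVParams, y0: np.ndarray, times: np.ndarray,
               rtol: float = 1e-8, atol: float = 1e-10,
               method: str = "RK45") -> np.ndarray:
    sol = solve_ivp(
        _lv_rhs_stacked,
        (float(times[0]), float(times[-1])),
        y0,
        t_eval=times,
        args=(params.r_s, params.r_r, params.K_s, params.K_r,
              params.alpha_sr, params.alpha_rs),
        rtol=rtol,
        atol=atol,
        method=method,
    )
    if not sol.success:
        raise RuntimeError(f"LV integration failed for {params}: {sol.message}")
    return sol.y


def simulate_lv(params: LVParams, initial, times, rtol: float = 1e-8,
                atol: float = 1e-10, method: str = "RK45"):
    """Integrate the two-clone system from ``initial = (x_s0, x_r0)``.

    Returns ``(x_s, x_r)`` arrays evaluated at ``times``.  ``method="RK4"``
    selects a fixed-step classic Runge-Kutta integration, useful for
    bit-reproducibility checks.
    """
    times = np.asarray(times, dtype=float)
    x_s0, x_r0 = (float(v) for v in initial)
    if x_s0 < 0 or x_r0 < 0:
        raise ValueError("initial abundances must be non-negative")
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing with >= 2 points")
    if method.upper() == "RK4":
        return _rk4(params, np.array([x_s0, x_r0]), times)
    y = _integrate(params, np.array([x_s0, x_r0]), times, rtol, atol, method)
    return y[0], y[1]


def _rk4(params: LVParams, y0, times, substeps: int = 20):
    args = (params.r_s, params.r_r, params.K_s, params.K_r,
            params.alpha_sr, params.alpha_rs)
    out = np.empty((y0.size, times.size))
    y = y0.astype(float).copy()
    out[:, 0] = y
    for i in range(times.size - 1):
        h = (times[i + 1] - times[i]) / substeps
        t = times[i]
        for _ in range(substeps):
            k1 = _lv_rhs_stacked(t, y, *args)
            k2 = _lv_rhs_stacked(t + h / 2, y + h / 2 * k1, *args)
            k3 = _lv_rhs_stacked(t + h / 2, y + h / 2 * k2, *args)
            k4 = _lv_rhs_stacked(t + h, y + h * k3, *args)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[:, i + 1] = y
    return out[0], out[1]


@dataclass
class _CocultureBlock:
    label: str
    fraction_s: float | None    # known seeding fraction of the sensitive clone
    times: np.ndarray           # shared sampling grid
    log_ys: np.ndarray          # replicate x time, log sensitive channel
    log_yr: np.ndarray          # replicate x time, log resistant channel


@dataclass
class _MonoBlock:
    clone: str                  # "s" or "r"
    times: np.ndarray
    log_y: np.ndarray           # replicate x time


class LotkaVolterraCompetition(BaseEstimator):
    """Fit the two-clone competition model to mono- and co-culture curves.

    The curves table is long-format with columns
    ``clone, replicate, channel, time_h, value`` where the ``clone`` column
    labels the culture condition.  Monoculture conditions are named by
    ``mono_s``/``mono_r``; all other conditions are co-cultures with both
    channels present.  Seeding fractions are read from co-culture labels of
    the form ``co_<pct_s>_<pct_r>`` (or supplied via ``seeding_fractions``);
    when unknown, both initial abundances of that co-culture are fitted.

    Parameters
    ----------
    channel_map : dict
        Maps channel labels to clones, e.g. ``{"yellow": "s", "red": "r"}``.
    mono_s, mono_r : str
        Condition labels of the two monocultures.
    seeding_fractions : dict or None
        Optional ``{co_label: fraction_sensitive}`` overriding label parsing.
    joint_refine : bool
        Refine all parameters jointly after the two-stage fit (default; the
        two-stage point estimate alone is kept for diagnostics).

    Attributes
    ----------
    params_ : LVParams
    ratio_ : float
        alpha_rs / alpha_sr.
    rss_ : float
        Residual sum of squares on the log scale (co-culture + monoculture).
    converged_ : bool
    bootstrap_ : pandas.DataFrame, set by :meth:`bootstrap`.
    """

    def __init__(self, channel_map: dict | None = None, mono_s: str = "mono_s",
                 mono_r: str = "mono_r", seeding_fractions: dict | None = None,
                 joint_refine: bool = True, rtol: float = 1e-8,
                 atol: float = 1e-10):
        self.channel_map = channel_map
        self.mono_s = mono_s
        self.mono_r = mono_r
        self.seeding_fractions = seeding_fractions
        self.joint_refine = joint_refine
        self.rtol = rtol
        self.atol = atol

    # ---------------------------------------------------------------- fitting
    def fit(self, curves: pd.DataFrame):
        cmap = self.channel_map or DEFAULT_CHANNEL_MAP
        conditions = set(curves["clone"].unique())
        if self.mono_s not in conditions or self.mono_r not in conditions:
            raise ValueError(
                f"need monoculture conditions {self.mono_s!r} and {self.mono_r!r}; "
                f"found {sorted(conditions)}"
            )
        co_labels = sorted(conditions - {self.mono_s, self.mono_r})
        if not co_labels:
            raise ValueError("need at least one co-culture condition")

        # stage 1: per-clone (r, K, x0) from monocultures, own channel only
        self.mono_fits_ = {}
        mono_blocks = []
        stage1 = {}
        for label, clone in ((self.mono_s, "s"), (self.mono_r, "r")):
            sub = curves[curves["clone"] == label]
            sub = sub[sub["channel"].map(cmap) == clone]
            if sub.empty:
                raise ValueError(
                    f"monoculture {label!r} has no channel mapping to {clone!r}")
            times = np.sort(sub["time_h"].unique()).astype(float)
            log_y, fits = [], []
            for _, g in sub.groupby("replicate"):
                g = g.sort_values("time_h")
                y = g["value"].to_numpy(dtype=float)
                if y.size != times.size:
                    raise ValueError(f"monoculture {label!r}: ragged time grid")
                fits.append(fit_logistic(times, y))
                log_y.append(np.log(np.maximum(y, 1e-12)))
            self.mono_fits_[clone] = fits
            mono_blocks.append(_MonoBlock(clone, times, np.array(log_y)))
            stage1[clone] = (
                float(np.mean([f.r_ for f in fits])),
                float(np.mean([f.K_ for f in fits])),
                float(np.mean([f.x0_ for f in fits])),
            )
        r_s, K_s, x0_s = stage1["s"]
        r_r, K_r, x0_r = stage1["r"]

        blocks = [self._block(curves, label, cmap) for label in co_labels]
        self.blocks_ = blocks
        self.mono_blocks_ = mono_blocks

        # stage 2: alphas + per-co-culture inocula on co-cultures only
        theta0, lower, upper = self._stage2_init(blocks, K_s, K_r)
        res2 = least_squares(
            self._stage2_resid, theta0, bounds=(lower, upper),
            args=(blocks, r_s, r_r, K_s, K_r), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        self.stage2_params_ = LVParams(r_s, r_r, K_s, K_r,
                                       float(res2.x[0]), float(res2.x[1]))

        if self.joint_refine:
            theta0 = np.concatenate([[r_s, r_r, K_s, K_r], res2.x[:2],
                                     [x0_s, x0_r], res2.x[2:]])
            res = self._joint_fit(theta0, blocks, mono_blocks)
            r_s, r_r, K_s, K_r, a_sr, a_rs, x0_s, x0_r = res.x[:8]
            self._co_inocula_ = res.x[8:]
        else:
            res = res2
            a_sr, a_rs = res2.x[0], res2.x[1]
            self._co_inocula_ = res2.x[2:]

        self._mono_x0_ = (float(x0_s), float(x0_r))
        self.params_ = LVParams(float(r_s), float(r_r), float(K_s), float(K_r),
                                float(a_sr), float(a_rs))
        self.rss_ = float(res.fun @ res.fun)
        self.diagnostic_ = None
        at_boundary = (a_sr <= 1e-6 or a_rs <= 1e-6
                       or a_sr >= 9.99 or a_rs >= 9.99)
        if at_boundary:
            self.diagnostic_ = (
                "competition coefficient on the boundary of its box; the "
                "co-cultures may be indistinguishable from monocultures"
            )
        self.converged_ = (bool(res.success) and not at_boundary
                           and self._identifiable(res))
        if a_sr <= 1e-9:
            self.ratio_ = np.inf if a_rs > 0 else np.nan
        else:
            self.ratio_ = float(a_rs / a_sr)
        return self

    def _block(self, curves, label, cmap):
        sub = curves[curves["clone"] == label]
        times = np.sort(sub["time_h"].unique()).astype(float)
        ys, yr = [], []
        for _, g in sub.groupby("replicate"):
            g = g.sort_values("time_h")
            s = g[g["channel"].map(cmap) == "s"]["value"].to_numpy(dtype=float)
            r = g[g["channel"].map(cmap) == "r"]["value"].to_numpy(dtype=float)
            if s.size != times.size or r.size != times.size:
                raise ValueError(f"co-culture {label!r}: channels on unequal grids")
            ys.append(np.log(np.maximum(s, 1e-12)))
            yr.append(np.log(np.maximum(r, 1e-12)))
        frac = (self.seeding_fractions or {}).get(label, self._parse_fraction(label))
        return _CocultureBlock(label, frac, times, np.array(ys), np.array(yr))

    @staticmethod
    def _parse_fraction(label: str) -> float | None:
        m = _CO_LABEL.search(str(label))
        if not m:
            return None
        fs, fr = float(m.group(1)), float(m.group(2))
        return fs / (fs + fr) if fs + fr > 0 else None

    # stage-2 parameter vector: [a_sr, a_rs] + per-block inoculum terms
    # (one total when the seeding fraction is known, else an (x_s0, x_r0) pair)
    def _stage2_init(self, blocks, K_s, K_r):
        theta0, lower, upper = [0.5, 0.5], [0.0, 0.0], [10.0, 10.0]
        kmax = max(K_s, K_r)
        for b in blocks:
            tot0 = float(np.exp(b.log_ys[:, 0]).mean()
                         + np.exp(b.log_yr[:, 0]).mean())
            if b.fraction_s is not None:
                theta0 += [tot0]
                lower += [1e-9]
                upper += [kmax]
            else:
                theta0 += [max(b.fraction_s or 0, 0) or tot0 / 2, tot0 / 2]
                lower += [1e-9, 1e-9]
                upper += [kmax, kmax]
        return np.array(theta0), np.array(lower), np.array(upper)

    def _co_y0(self, blocks, inocula):
        y0, k = [], 0
        for b in blocks:
            if b.fraction_s is not None:
                tot = inocula[k]
                y0 += [b.fraction_s * tot, (1.0 - b.fraction_s) * tot]
                k += 1
            else:
                y0 += [inocula[k], inocula[k + 1]]
                k += 2
        return np.asarray(y0)

    def _co_resid(self, params, blocks, inocula):
        res = []
        grids = {}
        for i, b in enumerate(blocks):
            grids.setdefault(tuple(b.times), []).append(i)
        y0_all = self._co_y0(blocks, inocula)
        offsets = np.concatenate([[0], np.cumsum([2] * len(blocks))])
        for tkey, idx in grids.items():
            times = np.asarray(tkey)
            y0 = np.concatenate([y0_all[offsets[i]:offsets[i] + 2] for i in idx])
            y = _integrate(params, y0, times, self.rtol, self.atol)
            for j, i in enumerate(idx):
                b = blocks[i]
                log_s = np.log(np.maximum(y[2 * j], 1e-12))
                log_r = np.log(np.maximum(y[2 * j + 1], 1e-12))
                res.append((b.log_ys - log_s).ravel())
                res.append((b.log_yr - log_r).ravel())
        return np.concatenate(res)

    def _stage2_resid(self, theta, blocks, r_s, r_r, K_s, K_r):
        params = LVParams(r_s, r_r, K_s, K_r,
                          max(theta[0], 0.0), max(theta[1], 0.0))
        return self._co_resid(params, blocks, theta[2:])

    def _joint_fit(self, theta0, blocks, mono_blocks, **ls_kwargs):
        def resid(theta):
            r_s, r_r, K_s, K_r, a_sr, a_rs, x0_s, x0_r = theta[:8]
            params = LVParams(r_s, r_r, K_s, K_r,
                              max(a_sr, 0.0), max(a_rs, 0.0))
            parts = [self._co_resid(params, blocks, theta[8:])]
            # monocultures decouple: closed-form logistic, no ODE needed
            for mb in mono_blocks:
                r, K, x0 = ((r_s, K_s, x0_s) if mb.clone == "s"
                            else (r_r, K_r, x0_r))
                log_m = np.log(np.maximum(logistic(mb.times, r, K, x0), 1e-12))
                parts.append((mb.log_y - log_m).ravel())
            return np.concatenate(parts)

        scale = max(p for p in theta0[2:4])
        lower = np.concatenate([[1e-5, 1e-5, 1e-3, 1e-3, 0.0, 0.0],
                                np.full(theta0.size - 6, 1e-9)])
        upper = np.concatenate([[1.0, 1.0, 100 * scale, 100 * scale, 10.0, 10.0],
                                np.full(theta0.size - 6, 10 * scale)])
        opts = dict(xtol=1e-12, ftol=1e-12, gtol=1e-12)
        opts.update(ls_kwargs)
        return least_squares(resid, np.clip(theta0, lower, upper),
                             bounds=(lower, upper), method="trf", **opts)

    @staticmethod
    def _identifiable(res) -> bool:
        # co-cultures indistinguishable from monocultures leave the alphas
        # flat; detect via vanishing sensitivity of residuals to the alphas
        J = res.jac
        if J is None:
            return True
        a_cols = slice(4, 6) if J.shape[1] >= 8 else slice(0, 2)
        col_norm = np.linalg.norm(J[:, a_cols], axis=0)
        scale = max(float(np.linalg.norm(res.fun)), 1.0)
        return bool(np.all(col_norm > 1e-10 * scale))

    # ------------------------------------------------------------- prediction
    def predict(self, label_or_index=0, times=None):
        """Fitted co-culture trajectories ``(x_s, x_r)`` for one condition."""
        check_is_fitted(self, "params_")
        labels = [b.label for b in self.blocks_]
        idx = (labels.index(label_or_index)
               if isinstance(label_or_index, str) else int(label_or_index))
        b = self.blocks_[idx]
        t = b.times if times is None else np.asarray(times, dtype=float)
        y0 = self._co_y0(self.blocks_, self._co_inocula_)[2 * idx:2 * idx + 2]
        return simulate_lv(self.params_, y0, t, rtol=self.rtol, atol=self.atol)

    # -------------------------------------------------------------- bootstrap
    def bootstrap(self, n_boot: int = 1000, seed: int | None = None):
        """Residual-resampling bootstrap of the competition coefficients.

        Log-scale residuals (matching the multiplicative error model) are
        resampled with replacement within each curve — monoculture and
        co-culture alike — and added back to the fitted trajectories; each
        resample is refitted with the full pipeline warm-started at the point
        estimate.  Per-resample random streams are spawned from ``seed`` so
        the first ``m`` resamples of a longer run coincide with an
        ``m``-resample run.  Sets ``bootstrap_`` (columns alpha_sr, alpha_rs,
        ratio, converged) and ``bootstrap_quantiles_`` (2.5/25/50/75/97.5%).
        """
        check_is_fitted(self, "params_")
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        p = self.params_
        x0_s, x0_r = self._mono_x0_

        # fitted log-trajectories and residuals for every curve
        co_fit = []
        y0_all = self._co_y0(self.blocks_, self._co_inocula_)
        for i, b in enumerate(self.blocks_):
            xs, xr = simulate_lv(p, y0_all[2 * i:2 * i + 2], b.times,
                                 rtol=self.rtol, atol=self.atol)
            co_fit.append((np.log(np.maximum(xs, 1e-12)),
                           np.log(np.maximum(xr, 1e-12))))
        mono_fit = []
        for mb in self.mono_blocks_:
            r, K, x0 = ((p.r_s, p.K_s, x0_s) if mb.clone == "s"
                        else (p.r_r, p.K_r, x0_r))
            mono_fit.append(np.log(np.maximum(logistic(mb.times, r, K, x0), 1e-12)))

        theta_hat = np.concatenate([
            [p.r_s, p.r_r, p.K_s, p.K_r, p.alpha_sr, p.alpha_rs, x0_s, x0_r],
            self._co_inocula_,
        ])
        streams = np.random.SeedSequence(seed).spawn(n_boot)
        rows = []
        for ss in streams:
            rng = np.random.default_rng(ss)
            blocks = []
            for (ls, lr), b in zip(co_fit, self.blocks_):
                new_s = np.empty_like(b.log_ys)
                new_r = np.empty_like(b.log_yr)
                for k in range(b.log_ys.shape[0]):
                    rs = b.log_ys[k] - ls
                    rr = b.log_yr[k] - lr
                    new_s[k] = ls + rng.choice(rs, rs.size, replace=True)
                    new_r[k] = lr + rng.choice(rr, rr.size, replace=True)
                blocks.append(_CocultureBlock(b.label, b.fraction_s, b.times,
                                              new_s, new_r))
            monos = []
            for lm, mb in zip(mono_fit, self.mono_blocks_):
                new = np.empty_like(mb.log_y)
                for k in range(mb.log_y.shape[0]):
                    rm = mb.log_y[k] - lm
                    new[k] = lm + rng.choice(rm, rm.size, replace=True)
                monos.append(_MonoBlock(mb.clone, mb.times, new))
            res = self._joint_fit(theta_hat, blocks, monos,
                                  xtol=1e-10, ftol=1e-10, gtol=1e-10,
                                  max_nfev=60)
            a_sr, a_rs = float(res.x[4]), float(res.x[5])
            rows.append({
                "alpha_sr": a_sr,
                "alpha_rs": a_rs,
                "ratio": a_rs / a_sr if a_sr > 1e-9 else np.inf,
                "converged": bool(res.success),
            })
        boot = pd.DataFrame(rows)
        self.bootstrap_ = boot
        self.bootstrap_warning_ = None
        frac_bad = 1.0 - boot["converged"].mean()
        if frac_bad > 0.2:
            self.bootstrap_warning_ = (
                f"{frac_bad:.0%} of bootstrap resamples failed to converge"
            )
        qs = [0.025, 0.25, 0.5, 0.75, 0.975]
        self.bootstrap_quantiles_ = {
            col: {q: float(boot[col].quantile(q)) for q in qs}
            for col in ("alpha_sr", "alpha_rs", "ratio")
        }
        return boot

    def report(self) -> dict:
        """JSON-serialisable fit report."""
        check_is_fitted(self, "params_")
        out = {
            "params": {
                "r_s": self.params_.r_s, "r_r": self.params_.r_r,
                "K_s": self.params_.K_s, "K_r": self.params_.K_r,
                "alpha_sr": self.params_.alpha_sr,
                "alpha_rs": self.params_.alpha_rs,
            },
            "ratio": self.ratio_,
            "rss": self.rss_,
            "converged": self.converged_,
        }
        if hasattr(self, "bootstrap_quantiles_"):
            out["bootstrap_quantiles"] = self.bootstrap_quantiles_
            out["bootstrap_warning"] = self.bootstrap_warning_
        return out


def fit_lv(curves: pd.DataFrame, **kwargs) -> LotkaVolterraCompetition:
    """Fit the LV competition model on a long-format curves table."""
    return LotkaVolterraCompetition(**kwargs).fit(curves)


def bootstrap_lv(curves: pd.DataFrame, n_boot: int = 1000,
                 seed: int | None = None, **kwargs) -> pd.DataFrame:
    """Fit then bootstrap; returns the resample DataFrame."""
    model = fit_lv(curves, **kwargs)
    return model.bootstrap(n_boot=n_boot, seed=seed)
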