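"""Morphology feature normalization, reduction and group testing.

Per-cell feature tables (e.g. CellProfiler shape/intensity/texture
measurements) are normalised by robust Z-scoring each feature to the median
and MAD of a reference population (the drug-sensitive clones), then passed
through an iterative feature-reduction step that removes inactive
(low-variance) features and one member of every highly correlated pair
(|Pearson r| above a cut, 0.85 by default).  Surviving features are compared
between groups with per-cell Welch t-tests, reported with Benjamini-Hochberg
adjusted p-values alongside the raw ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ReferenceRobustScaler",
    "CorrelationFeatureReducer",
    "robust_z_reference",
    "reduce_features",
    "test_features",
]

MAD_SCALE = 1.4826


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("cell_id", "group")]


class ReferenceRobustScaler(BaseEstimator, TransformerMixin):
    """Robust Z-scoring of features against a reference population.

    ``fit`` learns per-feature median and MAD from the reference rows;
    ``transform`` maps any table of the same features to
    z = (x - ref_median) / (1.4826 * ref_MAD).  Features whose reference MAD
    is zero — or negligible relative to the dataset's typical feature MAD
    (``mad_rtol`` times the median positive MAD), as produced by near-constant
    "inactive" measurements — are flagged in ``zero_mad_mask_`` and passed
    through centred but unscaled, so they remain near-constant and are caught
    by the downstream variance floor instead of being blown up by their own
    vanishing scale.

    Parameters
    ----------
    mad_rtol : float
        Relative threshold below which a reference MAD is treated as zero.
    """

    def __init__(self, mad_rtol: float = 1e-6):
        self.mad_rtol = mad_rtol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2D cells x features array")
        if X.shape[0] < 10:
            raise ValueError("reference population needs >= 10 cells")
        self.median_ = np.median(X, axis=0)
        self.mad_ = np.median(np.abs(X - self.median_), axis=0)
        positive = self.mad_[self.mad_ > 0]
        floor = self.mad_rtol * float(np.median(positive)) if positive.size else 0.0
        self.zero_mad_mask_ = self.mad_ <= floor
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "median_")
        X = np.asarray(X, dtype=float)
        scale = np.where(self.zero_mad_mask_, 1.0, MAD_SCALE * self.mad_)
        return (X - self.median_) / scale


def robust_z_reference(table: pd.DataFrame, reference_group: str = "negative",
                       group_col: str = "group"):
    """Normalise a long feature table against one group; drops NaN rows.

    Returns ``(normalized_table, stats)`` where stats has one row per feature
    (median, mad, zero_mad flag).  Rows with missing feature values are
    dropped and counted in ``normalized_table.attrs["n_dropped"]``.
    """
    feats = _feature_columns(table)
    n_before = len(table)
    table = table.dropna(subset=feats)
    ref = table[table[group_col] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} absent")
    scaler = ReferenceRobustScaler().fit(ref[feats].to_numpy())
    out = table.copy()
    out[feats] = scaler.transform(table[feats].to_numpy())
    out.attrs["n_dropped"] = n_before - len(table)
    stats_df = pd.DataFrame({
        "feature": feats,
        "median": scaler.median_,
        "mad": scaler.mad_,
        "zero_mad": scaler.zero_mad_mask_,
    })
    return out, stats_df


class CorrelationFeatureReducer(BaseEstimator, TransformerMixin):
    """Iterative variance / correlation feature reduction.

    Repeats until stable: (1) drop features with variance below ``var_floor``
    (inactive); (2) while any retained pair exceeds ``corr_cut`` in absolute
    Pearson correlation, drop one member of the worst pair — the feature with
    the higher mean absolute correlation to all other retained features, ties
    broken by name.  Every removal is logged with its reason and, for
    redundant features, the correlated partner.

    Attributes
    ----------
    retained_ : list of str
    removal_log_ : pandas.DataFrame with columns feature, reason, partner
    """

    def __init__(self, var_floor: float = 1e-3, corr_cut: float = 0.85):
        self.var_floor = var_floor
        self.corr_cut = corr_cut

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            feats = [c for c in X.columns if c not in ("cell_id", "group")]
            data = X[feats]
        else:
            data = pd.DataFrame(np.asarray(X, dtype=float))
            data.columns = [f"feat_{i}" for i in range(data.shape[1])]
            feats = list(data.columns)
        if len(feats) < 2:
            raise ValueError("feature reduction needs >= 2 features")

        retained = list(feats)
        log = []
        changed = True
        while changed:
            changed = False
            # inactive features
            variances = data[retained].var(ddof=1)
            for name in variances.index[variances < self.var_floor]:
                retained.remove(name)
                log.append({"feature": name, "reason": "inactive", "partner": None})
                changed = True
            # redundant features
            while len(retained) >= 2:
                corr = data[retained].corr().abs()
                np.fill_diagonal(corr.values, 0.0)
                if corr.values.max() <= self.corr_cut:
                    break
                i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
                a, b = corr.index[i], corr.columns[j]
                mean_abs = corr.mean()
                if mean_abs[a] > mean_abs[b]:
                    drop, keep = a, b
                elif mean_abs[a] < mean_abs[b]:
                    drop, keep = b, a
                else:
                    drop, keep = max(a, b), min(a, b)
                retained.remove(drop)
                log.append({"feature": drop, "reason": "redundant", "partner": keep})
                changed = True
        if not retained:
            raise ValueError(
                "all features removed; raise corr_cut or lower var_floor")
        self.retained_ = retained
        self.removal_log_ = pd.DataFrame(log, columns=["feature", "reason", "partner"])
        self.feature_names_in_ = list(feats)
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        if isinstance(X, pd.DataFrame):
            keep = [c for c in X.columns if c in ("cell_id", "group")]
            return X[keep + self.retained_]
        idx = [self.feature_names_in_.index(f) for f in self.retained_]
        return np.asarray(X, dtype=float)[:, idx]


def reduce_features(table: pd.DataFrame, var_floor: float = 1e-3,
                    corr_cut: float = 0.85) -> CorrelationFeatureReducer:
    """Fit the iterative reducer on a feature table (thin wrapper)."""
    return CorrelationFeatureReducer(var_floor=var_floor, corr_cut=corr_cut).fit(table)


def test_features(table: pd.DataFrame, group_a: str, group_b: str,
                  group_col: str = "group") -> pd.DataFrame:
    """Per-feature two-sided Welch t-tests between two cell groups.

    Returns one row per feature: statistic, raw p, Benjamini-Hochberg
    adjusted p, and a flag for degenerate features (zero variance in both
    groups, reported with p = 1).
    """
    feats = _feature_columns(table)
    a = table[table[group_col] == group_a]
    b = table[table[group_col] == group_b]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 cells")
    stats_out, pvals, degenerate = [], [], []
    for f in feats:
        xa, xb = a[f].to_numpy(), b[f].to_numpy()
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            stats_out.append(0.0)
            pvals.append(1.0)
            degenerate.append(True)
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        stats_out.append(float(t))
        pvals.append(float(p))
        degenerate.append(False)
    adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "feature": feats,
        "statistic": stats_out,
        "p_value": pvals,
        "p_adjusted": adj,
        "degenerate": degenerate,
    })
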