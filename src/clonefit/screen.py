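"""Multi-plate viability screen normalization and hit calling.

Raw per-well nuclear counts from a 384-well screen are normalised for plate
batch effects by fold change to the median of each plate's negative-control
(DMSO) wells, then robust Z-scored against the compound wells of the whole
dataset within each cell line.  Two decision rules follow:

* *primary hits*: fold change < 0.5 at one or more dose points in **every**
  required cell line;
* *validation nominations*: robust Z < -2 at a minimum of two dose points
  (by default on the mean-across-cell-lines dose profile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedScreen",
    "normalize_plates",
    "robust_z",
    "call_primary_hits",
    "nominate_validation_hits",
    "call_hits",
]

MAD_SCALE = 1.4826  # normal-consistency constant


@dataclass
class NormalizedScreen:
    wells: pd.DataFrame           # input columns + fold_change (+ robust_z)
    plate_controls: pd.DataFrame  # plate_id, median, mad, n
    z_fallback_lines: tuple = ()  # cell lines where MAD was 0 and SD was used


def normalize_plates(wells: pd.DataFrame) -> NormalizedScreen:
    """Fold change to the per-plate negative-control median.

    Requires a ``negative_control`` role with positive counts on every plate.
    The control median itself maps to fold change 1 by construction, so any
    per-plate multiplicative batch factor cancels exactly.
    """
    wells = wells.copy()
    summaries = []
    medians = {}
    for plate, grp in wells.groupby("plate_id"):
        ctrl = grp.loc[grp["role"] == "negative_control", "count"]
        if ctrl.empty:
            raise ValueError(f"plate {plate!r} has no negative-control wells")
        med = float(ctrl.median())
        if med <= 0:
            raise ValueError(f"plate {plate!r}: non-positive control median")
        medians[plate] = med
        summaries.append({
            "plate_id": plate, "median": med,
            "mad": float((ctrl - med).abs().median()), "n": int(ctrl.size),
        })
    wells["fold_change"] = wells["count"] / wells["plate_id"].map(medians)
    return NormalizedScreen(wells, pd.DataFrame(summaries))


def robust_z(values, center: float | None = None, scale: float | None = None,
             min_n: int = 10):
    """Robust Z-score: (x - median) / (1.4826 * MAD).

    Returns ``(z, used_sd_fallback)``.  When the MAD is zero the ordinary
    standard deviation takes its place (flagged); when both are zero all
    scores are 0 (also flagged).  ``min_n`` guards against meaningless scale
    estimates from very small reference populations.
    """
    x = np.asarray(values, dtype=float)
    if x.size < min_n:
        raise ValueError(f"robust Z-scoring needs >= {min_n} values")
    med = float(np.median(x)) if center is None else center
    mad = float(np.median(np.abs(x - med))) if scale is None else scale
    if mad > 0:
        return (x - med) / (MAD_SCALE * mad), False
    sd = float(np.std(x, ddof=1))
    if sd > 0:
        return (x - med) / sd, True
    return np.zeros_like(x), True


def add_robust_z(norm: NormalizedScreen, per_cell_line: bool = True) -> NormalizedScreen:
    """Robust Z-score fold changes against the dataset's compound wells.

    The reference population is all compound wells (controls excluded),
    per cell line by default.
    """
    wells = norm.wells.copy()
    wells["robust_z"] = np.nan
    fallback = []
    mask = wells["role"] == "compound"
    groups = wells[mask].groupby("cell_line") if per_cell_line else [(None, wells[mask])]
    for line, grp in groups:
        z, used_sd = robust_z(grp["fold_change"].to_numpy())
        wells.loc[grp.index, "robust_z"] = z
        if used_sd:
            fallback.append(line)
    return NormalizedScreen(wells, norm.plate_controls, tuple(fallback))


def _profile(norm: NormalizedScreen, value: str) -> pd.DataFrame:
    """compound x (cell_line, dose) table of replicate-mean values."""
    wells = norm.wells
    comp = wells[wells["role"] == "compound"]
    return comp.pivot_table(index="compound", columns=["cell_line", "dose_uM"],
                            values=value, aggfunc="mean")


def call_primary_hits(norm: NormalizedScreen, cell_lines=None,
                      threshold: float = 0.5, min_doses: int = 1) -> pd.DataFrame:
    """Primary hits: fold change < threshold at >= min_doses in all lines.

    Compounds missing any required cell line are excluded with a warning
    column rather than silently dropped.
    """
    prof = _profile(norm, "fold_change")
    lines = tuple(cell_lines) if cell_lines is not None else tuple(
        sorted(prof.columns.get_level_values(0).unique()))
    rows = []
    for compound, row in prof.iterrows():
        counts = {}
        missing = False
        for line in lines:
            if line not in row.index.get_level_values(0):
                missing = True
                break
            vals = row[line].dropna()
            if vals.empty:
                missing = True
                break
            counts[line] = int((vals < threshold).sum())
        if missing:
            rows.append({"compound": compound, "primary_hit": False,
                         "excluded_missing_line": True})
            continue
        rows.append({
            "compound": compound,
            "primary_hit": all(c >= min_doses for c in counts.values()),
            "excluded_missing_line": False,
            **{f"n_doses_below_{threshold}_{line}": c for line, c in counts.items()},
        })
    return pd.DataFrame(rows).set_index("compound")


def nominate_validation_hits(norm: NormalizedScreen, min_doses: int = 2,
                             z_cut: float = -2.0,
                             aggregate: str = "mean") -> pd.DataFrame:
    """Nominate compounds with robust Z < z_cut at >= min_doses dose points.

    ``aggregate="mean"`` tests the mean-across-cell-lines z profile per dose;
    ``aggregate="per_line"`` requires the criterion within every line.
    """
    if "robust_z" not in norm.wells.columns:
        norm = add_robust_z(norm)
    prof = _profile(norm, "robust_z")
    rows = []
    for compound, row in prof.iterrows():
        by_dose = row.unstack(0)  # dose x cell_line
        if aggregate == "mean":
            n_below = int((by_dose.mean(axis=1, skipna=True) < z_cut).sum())
            nominated = n_below >= min_doses
        elif aggregate == "per_line":
            per_line = (by_dose < z_cut).sum(axis=0)
            n_below = int(per_line.min())
            nominated = bool((per_line >= min_doses).all())
        else:
            raise ValueError(f"unknown aggregate mode {aggregate!r}")
        rows.append({"compound": compound, "nominated": nominated,
                     "n_doses_z_below_cut": n_below})
    return pd.DataFrame(rows).set_index("compound")


def call_hits(wells: pd.DataFrame, cell_lines=None, threshold: float = 0.5,
              z_cut: float = -2.0, min_doses_z: int = 2,
              aggregate: str = "mean") -> pd.DataFrame:
    """Full pipeline: normalise, z-score, primary hits and nominations."""
    norm = add_robust_z(normalize_plates(wells))
    primary = call_primary_hits(norm, cell_lines=cell_lines, threshold=threshold)
    nom = nominate_validation_hits(norm, min_doses=min_doses_z, z_cut=z_cut,
                                   aggregate=aggregate)
    return primary.join(nom)
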