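"""Readers, writers, run configuration and provenance records.

CSV dialect: comma-separated, UTF-8, '.' decimal, header required.  Numeric
outputs are written with 6 significant digits; in-memory comparisons are done
at full precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RunConfig",
    "read_timeseries_csv",
    "read_plate_csv",
    "read_features_csv",
    "write_table",
    "write_provenance",
]

TIMESERIES_COLUMNS = ["clone", "replicate", "channel", "time_h", "value"]
PLATE_COLUMNS = ["plate_id", "cell_line", "well", "row", "col", "role",
                 "compound", "dose_uM", "count"]


@dataclass
class RunConfig:
    """Stage parameters for a reproducible run; defaults mirror the shipped
    study conditions (dose ladders, thresholds, horizons)."""

    seed: int = 0
    output_dir: str = "out"
    sampling_interval_h: float = 12.0
    horizon_h: float = 264.0
    n_replicates: int = 4
    treatment_duration_h: float = 72.0
    primary_doses: tuple = (5.0, 0.5, 0.05)
    validation_doses: tuple = (10.0, 5.0, 2.25, 0.5, 0.225, 0.05)
    fold_change_threshold: float = 0.5
    z_cut: float = -2.0
    min_doses_z: int = 2
    corr_cut: float = 0.85
    var_floor: float = 1e-3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("primary_doses", "validation_doses"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["primary_doses"] = list(self.primary_doses)
        d["validation_doses"] = list(self.validation_doses)
        return d


def read_timeseries_csv(path) -> pd.DataFrame:
    """Read and validate a long-format growth-curve table.

    Checks the header, drops nothing silently: non-monotone times within a
    (clone, replicate, channel) series, negative or non-finite values raise
    with the offending rows' line numbers (1-based, counting the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[~np.isfinite(df["value"]) | (df["value"] < 0)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]
        raise ValueError(f"{path}: negative or non-finite values at lines {lines}")
    df = df.sort_values(["clone", "replicate", "channel", "time_h"],
                        kind="mergesort")
    for key, grp in df.groupby(["clone", "replicate", "channel"]):
        t = grp["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            dup = grp.index[1:][np.diff(t) <= 0][:5]
            lines = [int(i) + 2 for i in dup]
            raise ValueError(
                f"{path}: non-monotone times in series {key} near lines {lines}")
        if len(grp) < 5:
            raise ValueError(f"{path}: series {key} has fewer than 5 points")
    return df.reset_index(drop=True)


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns and c != "row"
               and c != "col"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("cell_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a table with 6-significant-digit numeric formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")


def write_provenance(output_dir, config: RunConfig | dict, **extra) -> Path:
    """Drop a provenance JSON (config, seed, package version) in output_dir."""
    from . import __version__

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "package": "clonefit",
        "version": __version__,
        "config": config.to_dict() if isinstance(config, RunConfig) else dict(config),
        **extra,
    }
    path = output_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path
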