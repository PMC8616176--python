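"""Synthetic data generators with ground-truth sidecars.

Every input the analysis stages consume can be generated here: single-clone
logistic growth curves, two-channel sensitive/resistant co-cultures governed by
Lotka-Volterra competition, 384-well drug-screen plate tables with per-plate
batch factors and planted hits, four-parameter-logistic dose-response viability
tables (including mixtures of a sensitive and a resistant clone), and per-cell
morphology feature tables with correlated blocks, inactive features and group
shifts.

All draws flow from a single integer seed through ``numpy.random.default_rng``;
identical (spec, seed) pairs produce byte-identical tables.  Each generator
returns ``(table, ground_truth)`` where the ground-truth dict mirrors every
generating parameter.

The shipped clone presets encode the study conditions the package targets: a
drug-sensitive (fusion-negative) clone doubling every 22 h and a resistant
(fusion-positive) clone doubling every 44 h, with the resistant clone suffering
a 3.5-fold stronger crowding effect from the sensitive clone than vice versa.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .competition import LVParams, simulate_lv
from .growth import logistic

__all__ = [
    "ClonePreset",
    "CompetitionPreset",
    "ScreenSpec",
    "ScreenHit",
    "MorphSpec",
    "FUSION_NEGATIVE",
    "FUSION_POSITIVE",
    "COMPETITION_DEFAULT",
    "get_preset",
    "make_clone_panel",
    "make_growth_curves",
    "make_coculture",
    "make_screen",
    "make_dose_response",
    "make_morphology",
]

DEFAULT_SAMPLING_H = 12.0
DEFAULT_HORIZON_H = 264.0
DEFAULT_REPLICATES = 4
NOISE_FLOOR = -0.9  # truncation of the multiplicative noise term


@dataclass(frozen=True)
class ClonePreset:
    """Logistic growth parameters of one clone."""

    label: str
    fusion_status: str  # "negative" (drug-sensitive) or "positive" (resistant)
    r: float            # intrinsic growth rate, 1/h
    K: float            # carrying capacity, signal units
    x0: float           # initial signal
    noise_cv: float = 0.05

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError(f"{self.label}: growth rate must be positive")
        if not (self.K > self.x0 > 0):
            raise ValueError(f"{self.label}: need K > x0 > 0")
        if self.noise_cv < 0:
            raise ValueError(f"{self.label}: noise_cv must be >= 0")
        if self.fusion_status not in ("negative", "positive"):
            raise ValueError(f"{self.label}: bad fusion_status {self.fusion_status!r}")

    @property
    def doubling_time(self) -> float:
        return float(np.log(2) / self.r)


@dataclass(frozen=True)
class CompetitionPreset:
    """Two-clone co-culture scenario."""

    clone_s: ClonePreset
    clone_r: ClonePreset
    alpha_sr: float  # effect of resistant on sensitive
    alpha_rs: float  # effect of sensitive on resistant
    seeding_ratios: tuple = ((0.25, 0.75), (0.5, 0.5), (0.75, 0.25))

    def __post_init__(self):
        if self.alpha_sr < 0 or self.alpha_rs < 0:
            raise ValueError("competition coefficients must be >= 0")
        for fs, fr in self.seeding_ratios:
            if abs(fs + fr - 1.0) > 1e-9:
                raise ValueError(f"seeding ratio ({fs}, {fr}) does not sum to 1")

    def lv_params(self) -> LVParams:
        return LVParams(self.clone_s.r, self.clone_r.r, self.clone_s.K,
                        self.clone_r.K, self.alpha_sr, self.alpha_rs)


# Shipped presets: sensitive clones double in 22 h, resistant in 44 h, and the
# crowding effect of sensitive on resistant is 3.5x the reverse.  The inoculum
# x0 is set so the noiseless curves reach 50% confluency at the observed mean
# times (62.46 h sensitive, 135.38 h resistant): x0 = K / (1 + e^{r t50}).
_R_NEG = float(np.log(2) / 22.0)
_R_POS = float(np.log(2) / 44.0)
FUSION_NEGATIVE = ClonePreset("fusion_negative", "negative", r=_R_NEG, K=100.0,
                              x0=float(100.0 / (1.0 + np.exp(_R_NEG * 62.46))))
FUSION_POSITIVE = ClonePreset("fusion_positive", "positive", r=_R_POS, K=100.0,
                              x0=float(100.0 / (1.0 + np.exp(_R_POS * 135.38))))
COMPETITION_DEFAULT = CompetitionPreset(
    clone_s=FUSION_NEGATIVE, clone_r=FUSION_POSITIVE,
    alpha_sr=0.2, alpha_rs=0.7,
)

_PRESETS = {
    "fusion_negative": FUSION_NEGATIVE,
    "fusion_positive": FUSION_POSITIVE,
    "competition_default": COMPETITION_DEFAULT,
}


def get_preset(name: str):
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")


def make_clone_panel(preset: ClonePreset, n_clones: int,
                     prefix: str | None = None) -> list[ClonePreset]:
    """``n_clones`` identically-parameterised clones with distinct labels."""
    prefix = prefix or preset.label
    return [
        ClonePreset(f"{prefix}_{i + 1}", preset.fusion_status, preset.r,
                    preset.K, preset.x0, preset.noise_cv)
        for i in range(n_clones)
    ]


def _mult_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    """Multiplicative factor 1 + eps, eps ~ N(0, cv^2) truncated at -0.9."""
    if cv == 0:
        return np.ones(shape)
    return 1.0 + np.maximum(rng.normal(0.0, cv, shape), NOISE_FLOOR)


# --------------------------------------------------------------------- growth
def make_growth_curves(presets, sampling_interval_h: float = DEFAULT_SAMPLING_H,
                       horizon_h: float = DEFAULT_HORIZON_H,
                       n_replicates: int = DEFAULT_REPLICATES,
                       seed: int | None = None):
    """Logistic growth trajectories for a list of clone presets.

    Returns a long-format DataFrame (clone, replicate, channel, time_h, value)
    sampled every ``sampling_interval_h`` hours up to ``horizon_h`` plus a
    ground-truth dict keyed by clone label.
    """
    if horizon_h < 2 * sampling_interval_h:
        raise ValueError("horizon must cover at least two sampling intervals")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    times = np.arange(0.0, horizon_h + 1e-9, sampling_interval_h)
    rng = np.random.default_rng(seed)
    frames = []
    truth = {"seed": seed, "sampling_interval_h": sampling_interval_h,
             "horizon_h": horizon_h, "n_replicates": n_replicates, "clones": {}}
    for preset in presets:
        clean = logistic(times, preset.r, preset.K, preset.x0)
        truth["clones"][preset.label] = asdict(preset)
        for rep in range(1, n_replicates + 1):
            values = clean * _mult_noise(rng, times.shape, preset.noise_cv)
            frames.append(pd.DataFrame({
                "clone": preset.label,
                "replicate": rep,
                "channel": "phase",
                "time_h": times,
                "value": values,
            }))
    return pd.concat(frames, ignore_index=True), truth


# ------------------------------------------------------------------ coculture
def make_coculture(preset: CompetitionPreset = COMPETITION_DEFAULT,
                   sampling_interval_h: float = DEFAULT_SAMPLING_H,
                   horizon_h: float = DEFAULT_HORIZON_H,
                   n_replicates: int = DEFAULT_REPLICATES,
                   seed: int | None = None):
    """Two-channel mono- and co-culture curves from the LV competition model.

    Monocultures of each clone plus co-cultures at every seeding ratio of the
    preset; the ``yellow`` channel reports the sensitive clone and ``red`` the
    resistant one.  The total seeded signal of a co-culture equals the mean of
    the two monoculture inocula and is split by the seeding fractions.
    Conditions are labelled ``mono_s``, ``mono_r`` and ``co_<pct_s>_<pct_r>``.
    """
    if horizon_h < 2 * sampling_interval_h:
        raise ValueError("horizon must cover at least two sampling intervals")
    times = np.arange(0.0, horizon_h + 1e-9, sampling_interval_h)
    rng = np.random.default_rng(seed)
    params = preset.lv_params()
    x0_total = 0.5 * (preset.clone_s.x0 + preset.clone_r.x0)

    conditions = [("mono_s", preset.clone_s.x0, 0.0),
                  ("mono_r", 0.0, preset.clone_r.x0)]
    for fs, fr in preset.seeding_ratios:
        label = f"co_{round(fs * 100)}_{round(fr * 100)}"
        conditions.append((label, fs * x0_total, fr * x0_total))

    frames = []
    truth = {
        "seed": seed, "sampling_interval_h": sampling_interval_h,
        "horizon_h": horizon_h, "n_replicates": n_replicates,
        "clone_s": asdict(preset.clone_s), "clone_r": asdict(preset.clone_r),
        "alpha_sr": preset.alpha_sr, "alpha_rs": preset.alpha_rs,
        "seeding_ratios": list(preset.seeding_ratios),
        "conditions": {},
    }
    for label, xs0, xr0 in conditions:
        try:
            xs, xr = simulate_lv(params, (xs0, xr0), times)
        except RuntimeError as err:
            raise RuntimeError(f"co-culture generation failed for {label}: {err}")
        truth["conditions"][label] = {"x_s0": xs0, "x_r0": xr0}
        for rep in range(1, n_replicates + 1):
            for channel, clean, cv in (
                ("yellow", xs, preset.clone_s.noise_cv),
                ("red", xr, preset.clone_r.noise_cv),
            ):
                values = clean * _mult_noise(rng, times.shape, cv)
                frames.append(pd.DataFrame({
                    "clone": label, "replicate": rep, "channel": channel,
                    "time_h": times, "value": values,
                }))
    return pd.concat(frames, ignore_index=True), truth


# --------------------------------------------------------------------- screen
PRIMARY_DOSES = (5.0, 0.5, 0.05)
VALIDATION_DOSES = (10.0, 5.0, 2.25, 0.5, 0.225, 0.05)
DEFAULT_CELL_LINES = ("sensitive_1", "sensitive_2", "resistant_1", "resistant_2")


@dataclass(frozen=True)
class ScreenHit:
    """Planted true effect: per-dose surviving fraction of a compound."""

    compound: str
    viability: tuple  # one fraction per dose, or a single repeated fraction


@dataclass
class ScreenSpec:
    """A multi-plate 384-well viability screen, one plate per cell line."""

    n_compounds: int = 100
    doses: tuple = PRIMARY_DOSES
    cell_lines: tuple = DEFAULT_CELL_LINES
    n_controls: int = 16
    baseline_count: float = 1000.0
    count_noise_cv: float = 0.1
    batch_factors: dict = field(default_factory=dict)  # plate_id -> factor
    batch_sigma: float = 0.2  # lognormal sigma for unspecified plates
    planted_hits: tuple = ()  # of ScreenHit

    def __post_init__(self):
        if self.n_controls < 8:
            raise ValueError("every plate needs >= 8 negative-control wells")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be strictly positive")
        if self.n_compounds * len(self.doses) + self.n_controls > 384:
            raise ValueError("layout exceeds 384 wells")


def _well_names():
    for row in string.ascii_uppercase[:16]:
        for col in range(1, 25):
            yield f"{row}{col:02d}", row, col


def make_screen(spec: ScreenSpec, seed: int | None = None):
    """Generate per-well counts: baseline x batch x true viability x noise."""
    rng = np.random.default_rng(seed)
    hit_map = {}
    for hit in spec.planted_hits:
        v = hit.viability
        if np.isscalar(v):
            v = tuple([float(v)] * len(spec.doses))
        if len(v) != len(spec.doses):
            raise ValueError(
                f"hit {hit.compound!r}: {len(v)} viabilities for {len(spec.doses)} doses"
            )
        hit_map[hit.compound] = tuple(float(x) for x in v)

    compounds = [f"cmpd_{i + 1:04d}" for i in range(spec.n_compounds)]
    unknown = set(hit_map) - set(compounds)
    if unknown:
        raise ValueError(f"planted hits reference unknown compounds: {sorted(unknown)}")

    rows = []
    truth = {"seed": seed, "doses": list(spec.doses),
             "cell_lines": list(spec.cell_lines),
             "baseline_count": spec.baseline_count,
             "count_noise_cv": spec.count_noise_cv,
             "planted_hits": {c: list(v) for c, v in hit_map.items()},
             "batch_factors": {}}
    for line in spec.cell_lines:
        plate_id = f"plate_{line}"
        batch = spec.batch_factors.get(
            plate_id,
            spec.batch_factors.get(
                line, float(rng.lognormal(0.0, spec.batch_sigma))
            ),
        )
        truth["batch_factors"][plate_id] = batch
        wells = _well_names()
        for _ in range(spec.n_controls):
            well, row, col = next(wells)
            count = spec.baseline_count * batch * float(
                _mult_noise(rng, (), spec.count_noise_cv))
            rows.append((plate_id, line, well, row, col, "negative_control",
                         None, np.nan, count))
        for compound in compounds:
            via = hit_map.get(compound, tuple([1.0] * len(spec.doses)))
            for dose, v in zip(spec.doses, via):
                well, row, col = next(wells)
                count = spec.baseline_count * batch * v * float(
                    _mult_noise(rng, (), spec.count_noise_cv))
                rows.append((plate_id, line, well, row, col, "compound",
                             compound, dose, count))
    table = pd.DataFrame(rows, columns=[
        "plate_id", "cell_line", "well", "row", "col", "role",
        "compound", "dose_uM", "count",
    ])
    return table, truth


# -------------------------------------------------------------- dose-response
def _survival_4pl(d, ec50, hill, top=1.0, bottom=0.0):
    d = np.asarray(d, dtype=float)
    return bottom + (top - bottom) / (1.0 + (d / ec50) ** hill)


def make_dose_response(params_neg: dict, doses, n_replicates: int = 3,
                       seed: int | None = None, params_pos: dict | None = None,
                       fraction_positive: float = 0.0,
                       control_count: float = 1000.0,
                       x0_count: float = 125.0,
                       noise_cv: float = 0.05,
                       sample_id: str | None = None):
    """Viability counts for a clone or a sensitive/resistant mixture.

    ``params_neg``/``params_pos`` are 4PL survival parameter dicts with keys
    ``ec50``, ``hill`` and optional ``top``/``bottom``.  A mixture with
    positive-cell fraction ``f`` survives ``(1-f) S_neg(d) + f S_pos(d)``.
    Emits treated wells plus vehicle-control and time-zero rows (roles
    ``treated``/``control``/``time0``) so growth-rate-corrected metrics can be
    computed downstream.
    """
    f = float(fraction_positive)
    if not (0.0 <= f <= 1.0):
        raise ValueError("fraction_positive must lie in [0, 1]")
    if f > 0 and params_pos is None:
        raise ValueError("params_pos required when fraction_positive > 0")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    for p in (params_neg, params_pos or params_neg):
        if p["ec50"] <= 0 or p["hill"] <= 0:
            raise ValueError("4PL ec50 and hill must be positive")

    s = (1.0 - f) * _survival_4pl(doses, **params_neg)
    if f > 0:
        s = s + f * _survival_4pl(doses, **params_pos)

    rng = np.random.default_rng(seed)
    sid = sample_id or (f"mix_{f:.2f}" if 0 < f < 1 else
                        ("pos" if f == 1.0 else "neg"))
    rows = []
    for rep in range(1, n_replicates + 1):
        rows.append((sid, rep, "time0", np.nan,
                     x0_count * float(_mult_noise(rng, (), noise_cv))))
        rows.append((sid, rep, "control", np.nan,
                     control_count * float(_mult_noise(rng, (), noise_cv))))
        for d, surv in zip(doses, s):
            count = control_count * surv * float(_mult_noise(rng, (), noise_cv))
            rows.append((sid, rep, "treated", d, count))
    table = pd.DataFrame(rows, columns=["sample", "replicate", "role",
                                        "dose_uM", "count"])
    truth = {"seed": seed, "sample": sid, "params_neg": dict(params_neg),
             "params_pos": dict(params_pos) if params_pos else None,
             "fraction_positive": f, "doses": doses.tolist(),
             "control_count": control_count, "x0_count": x0_count,
             "noise_cv": noise_cv, "true_survival": s.tolist()}
    return table, truth


# ----------------------------------------------------------------- morphology
@dataclass
class MorphSpec:
    """Two-group per-cell feature table (reference group first)."""

    n_cells_per_group: int = 500
    n_features: int = 148
    n_inactive: int = 10
    corr_blocks: tuple = ()          # of (block_size, target_pearson_r)
    group_shift: float | np.ndarray = 0.0  # per-feature shift, scaled-MAD units
    inactive_sd: float = 1e-8
    groups: tuple = ("negative", "positive")

    def __post_init__(self):
        n_block = sum(int(b) for b, _ in self.corr_blocks)
        if self.n_inactive + n_block > self.n_features:
            raise ValueError("inactive + correlated-block features exceed n_features")
        for _, r in self.corr_blocks:
            if abs(r) > 1.0:
                raise ValueError(f"infeasible correlation target {r}")


def make_morphology(spec: MorphSpec, seed: int | None = None):
    """Gaussian feature table: correlated blocks, inactive and free features.

    Features are unit-variance Gaussians (inactive ones have SD
    ``spec.inactive_sd``); the second group is shifted by ``group_shift``
    per feature, expressed in units of the reference's scaled MAD
    (1.4826 x MAD, which is ~1 SD for a Gaussian feature, so the shift is
    directly a robust-Z displacement).  Columns: cell_id, group, feat_*.
    """
    rng = np.random.default_rng(seed)
    n, p = spec.n_cells_per_group, spec.n_features
    total = 2 * n
    X = np.empty((total, p))
    kinds = []
    j = 0
    for size, r in spec.corr_blocks:
        size = int(size)
        cov = np.full((size, size), float(r))
        np.fill_diagonal(cov, 1.0)
        X[:, j:j + size] = rng.multivariate_normal(
            np.zeros(size), cov, size=total, method="svd")
        kinds += [f"corr_block_r{r}"] * size
        j += size
    for _ in range(spec.n_inactive):
        X[:, j] = rng.normal(0.0, spec.inactive_sd, total)
        kinds.append("inactive")
        j += 1
    while j < p:
        X[:, j] = rng.normal(0.0, 1.0, total)
        kinds.append("free")
        j += 1

    shift = np.broadcast_to(np.asarray(spec.group_shift, dtype=float), (p,)).copy()
    active = np.array([k != "inactive" for k in kinds])
    X[n:, active] += shift[active]

    names = [f"feat_{i + 1:03d}" for i in range(p)]
    table = pd.DataFrame(X, columns=names)
    table.insert(0, "group", np.repeat(list(spec.groups), n))
    table.insert(0, "cell_id", [f"cell_{i + 1:05d}" for i in range(total)])
    truth = {"seed": seed, "n_cells_per_group": n, "n_features": p,
             "feature_kind": dict(zip(names, kinds)),
             "group_shift": shift.tolist(),
             "corr_blocks": [list(b) for b in spec.corr_blocks],
             "n_inactive": spec.n_inactive}
    return table, truth
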