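"""Generator behaviour: determinism, noiseless exactness, planted structure."""

import numpy as np
import pandas as pd
import pytest

from clonefit import datasets, logistic
from clonefit.datasets import (ClonePreset, CompetitionPreset, MorphSpec,
                               ScreenHit, ScreenSpec)


def test_shipped_presets_encode_doubling_times():
    assert datasets.FUSION_NEGATIVE.doubling_time == pytest.approx(22.0)
    assert datasets.FUSION_POSITIVE.doubling_time == pytest.approx(44.0)
    # default competition asymmetry: sensitive suppresses resistant 3.5x more
    pre = datasets.COMPETITION_DEFAULT
    assert pre.alpha_rs / pre.alpha_sr == pytest.approx(3.5)


@pytest.mark.parametrize("bad", [
    dict(r=-0.01), dict(K=0.5), dict(x0=0.0), dict(noise_cv=-0.1),
])
def test_clone_preset_validation(bad):
    kwargs = dict(label="c", fusion_status="negative", r=0.03, K=100.0, x0=1.0,
                  noise_cv=0.05)
    kwargs.update(bad)
    with pytest.raises(ValueError):
        ClonePreset(**kwargs)


def test_growth_curves_deterministic_and_traceable():
    presets = [datasets.FUSION_NEGATIVE, datasets.FUSION_POSITIVE]
    a, truth = datasets.make_growth_curves(presets, seed=5)
    b, _ = datasets.make_growth_curves(presets, seed=5)
    pd.testing.assert_frame_equal(a, b)
    # ground-truth sidecar round-trips: rebuild presets from it
    rebuilt = [ClonePreset(**p) for p in truth["clones"].values()]
    c, _ = datasets.make_growth_curves(
        rebuilt, truth["sampling_interval_h"], truth["horizon_h"],
        truth["n_replicates"], truth["seed"])
    pd.testing.assert_frame_equal(a, c)


def test_noiseless_growth_equals_closed_form(times_12h):
    preset = ClonePreset("c", "negative", 0.03151, 100.0, 1.0, noise_cv=0.0)
    curves, _ = datasets.make_growth_curves([preset], seed=123, n_replicates=2)
    for _, grp in curves.groupby("replicate"):
        np.testing.assert_allclose(
            grp["value"].to_numpy(),
            logistic(grp["time_h"].to_numpy(), 0.03151, 100.0, 1.0),
            rtol=0, atol=0)


def test_noiseless_signal_reaches_half_capacity_at_analytic_time():
    # with K = 2 x threshold the crossing time is ln((K-x0)/x0)/r = 145.8 h
    preset = ClonePreset("c", "negative", 0.03151, 100.0, 1.0, noise_cv=0.0)
    t_half = np.log(99.0) / 0.03151
    assert t_half == pytest.approx(145.8, abs=0.1)
    curves, _ = datasets.make_growth_curves(
        [preset], sampling_interval_h=t_half, horizon_h=2 * t_half,
        n_replicates=1, seed=0)
    assert float(curves["value"].iloc[1]) == pytest.approx(50.0, abs=0.1)


def test_growth_curve_generator_validation():
    preset = datasets.FUSION_NEGATIVE
    with pytest.raises(ValueError):
        datasets.make_growth_curves([preset], sampling_interval_h=100.0,
                                    horizon_h=150.0, seed=0)


def test_coculture_without_competition_matches_monoculture_logistic(
        noiseless_competition_preset):
    pre = noiseless_competition_preset
    decoupled = CompetitionPreset(pre.clone_s, pre.clone_r, 0.0, 0.0,
                                  pre.seeding_ratios)
    curves, truth = datasets.make_coculture(decoupled, seed=0)
    x0_tot = 0.5 * (pre.clone_s.x0 + pre.clone_r.x0)
    for label, (fs, fr) in zip(
            [f"co_{round(a*100)}_{round(b*100)}" for a, b in pre.seeding_ratios],
            pre.seeding_ratios):
        sub = curves[(curves["clone"] == label) & (curves["replicate"] == 1)]
        for channel, clone, frac in (("yellow", pre.clone_s, fs),
                                     ("red", pre.clone_r, fr)):
            got = sub[sub["channel"] == channel].sort_values("time_h")
            expected = logistic(got["time_h"].to_numpy(), clone.r, clone.K,
                                frac * x0_tot)
            np.testing.assert_allclose(got["value"].to_numpy(), expected,
                                       atol=1e-8)


def test_coculture_sensitive_dominates_late(noiseless_coculture):
    curves, _ = noiseless_coculture
    co = curves[curves["clone"].str.startswith("co_")]
    last = co[co["time_h"] == co["time_h"].max()]
    for label, grp in last.groupby("clone"):
        y = grp[grp["channel"] == "yellow"]["value"].mean()
        r = grp[grp["channel"] == "red"]["value"].mean()
        assert y > r, f"sensitive channel should dominate late in {label}"


def test_coculture_long_horizon_reaches_coexistence_equilibrium():
    # closed form: x_s* = K(1-a_sr)/(1-a_sr a_rs), x_r* = K(1-a_rs)/(1-a_sr a_rs)
    eq = ClonePreset("e", "negative", 0.05, 100.0, 1.0, 0.0)
    pre = CompetitionPreset(eq, ClonePreset("f", "positive", 0.05, 100.0, 1.0, 0.0),
                            alpha_sr=0.2, alpha_rs=0.7,
                            seeding_ratios=((0.5, 0.5),))
    curves, _ = datasets.make_coculture(pre, sampling_interval_h=200.0,
                                        horizon_h=4000.0, n_replicates=1, seed=0)
    last = curves[(curves["clone"] == "co_50_50")
                  & (curves["time_h"] == curves["time_h"].max())]
    xs = last[last["channel"] == "yellow"]["value"].iloc[0]
    xr = last[last["channel"] == "red"]["value"].iloc[0]
    assert xr / (xs + xr) == pytest.approx(0.273, abs=0.01)


def test_screen_batch_factor_construction():
    spec = ScreenSpec(n_compounds=10, batch_factors={"plate_sensitive_1": 2.0,
                                                     "plate_sensitive_2": 1.0,
                                                     "plate_resistant_1": 1.0,
                                                     "plate_resistant_2": 1.0})
    table, truth = datasets.make_screen(spec, seed=0)
    ctrl = table[table["role"] == "negative_control"]
    doubled = ctrl[ctrl["plate_id"] == "plate_sensitive_1"]["count"].median()
    normal = ctrl[ctrl["plate_id"] == "plate_sensitive_2"]["count"].median()
    assert doubled / normal == pytest.approx(2.0, rel=0.1)
    assert truth["batch_factors"]["plate_sensitive_1"] == 2.0


def test_screen_spec_validation():
    with pytest.raises(ValueError):
        ScreenSpec(n_controls=4)
    with pytest.raises(ValueError):
        ScreenSpec(doses=(5.0, 0.0))
    with pytest.raises(ValueError):
        datasets.make_screen(
            ScreenSpec(planted_hits=(ScreenHit("nope", 0.3),)), seed=0)


def test_dose_response_mixture_endpoints_reduce_to_pure_curves():
    doses = np.geomspace(0.01, 10, 6)
    neg = {"ec50": 1.0, "hill": 1.0}
    pos = {"ec50": 10.0, "hill": 1.0}
    pure, _ = datasets.make_dose_response(neg, doses, seed=9, sample_id="x")
    zero, _ = datasets.make_dose_response(neg, doses, seed=9, params_pos=pos,
                                          fraction_positive=0.0, sample_id="x")
    pd.testing.assert_frame_equal(pure, zero)
    pure_pos, _ = datasets.make_dose_response(pos, doses, seed=9, sample_id="x")
    one, _ = datasets.make_dose_response(neg, doses, seed=9, params_pos=pos,
                                         fraction_positive=1.0, sample_id="x")
    pd.testing.assert_frame_equal(pure_pos, one)
    with pytest.raises(ValueError):
        datasets.make_dose_response(neg, doses, seed=9, params_pos=pos,
                                    fraction_positive=1.5)


def test_morphology_correlation_block_achieves_target():
    spec = MorphSpec(n_cells_per_group=500, n_features=4, n_inactive=0,
                     corr_blocks=((2, 0.95),))
    table, truth = datasets.make_morphology(spec, seed=11)
    x = table[["feat_001", "feat_002"]].to_numpy()
    r = np.corrcoef(x.T)[0, 1]
    assert 0.90 < r < 0.99
    assert truth["feature_kind"]["feat_001"].startswith("corr_block")


def test_morphology_spec_validation():
    with pytest.raises(ValueError):
        MorphSpec(n_features=5, n_inactive=2, corr_blocks=((4, 0.5),))
    with pytest.raises(ValueError):
        MorphSpec(corr_blocks=((2, 1.5),))


def test_generators_are_seed_deterministic():
    spec = ScreenSpec(n_compounds=5)
    a, _ = datasets.make_screen(spec, seed=3)
    b, _ = datasets.make_screen(spec, seed=3)
    pd.testing.assert_frame_equal(a, b)
    m = MorphSpec(n_cells_per_group=20, n_features=6, n_inactive=1)
    c, _ = datasets.make_morphology(m, seed=3)
    d, _ = datasets.make_morphology(m, seed=3)
    pd.testing.assert_frame_equal(c, d)
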