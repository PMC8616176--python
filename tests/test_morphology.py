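"""Reference robust Z-scoring, feature reduction and per-feature testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonefit import datasets, reduce_features, robust_z_reference
from clonefit import test_features as run_feature_tests
from clonefit.datasets import MorphSpec
from clonefit.morphology import CorrelationFeatureReducer, ReferenceRobustScaler


def _table(ref_values, other_values, feature="feat_001"):
    n_ref, n_other = len(ref_values), len(other_values)
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n_ref + n_other)],
        "group": ["negative"] * n_ref + ["positive"] * n_other,
        feature: list(ref_values) + list(other_values),
    })


def test_reference_median_maps_to_zero_and_worked_example():
    # reference with median 2 and raw MAD 1
    ref = [0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0]
    table = _table(ref, [100.0, 2.0])
    normed, stats = robust_z_reference(table)
    pos = normed[normed["group"] == "positive"]["feat_001"].to_numpy()
    assert pos[0] == pytest.approx((100.0 - 2.0) / 1.4826, abs=0.01)  # 66.10
    assert pos[0] == pytest.approx(66.10, abs=0.01)
    assert pos[1] == pytest.approx(0.0)
    assert stats.loc[0, "median"] == 2.0 and stats.loc[0, "mad"] == 1.0


@settings(max_examples=40, derandomize=True)
@given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
def test_affine_invariance_of_robust_z(a, b):
    rng = np.random.default_rng(7)
    ref = rng.normal(size=50)
    other = rng.normal(size=20)
    base = robust_z_reference(_table(ref, other))[0]
    transformed = robust_z_reference(_table(a * ref + b, a * other + b))[0]
    np.testing.assert_allclose(transformed["feat_001"], base["feat_001"],
                               rtol=1e-9, atol=1e-9)


def test_missing_reference_group_raises():
    table = _table([1.0] * 10, [2.0] * 5)
    with pytest.raises(ValueError, match="absent"):
        robust_z_reference(table, reference_group="bogus")
    ReferenceRobustScaler().fit(np.random.default_rng(0).normal(size=(10, 3)))
    with pytest.raises(ValueError):
        ReferenceRobustScaler().fit(np.zeros((5, 3)))


def test_six_feature_reduction_fixture():
    """One constant + one r=0.95 pair + three independent -> 4 retained."""
    rng = np.random.default_rng(3)
    n = 400
    x = rng.normal(size=n)
    table = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "group": "negative",
        "feat_const": np.zeros(n),
        "feat_a": x,
        "feat_b": 0.95 * x + np.sqrt(1 - 0.95 ** 2) * rng.normal(size=n),
        "feat_c": rng.normal(size=n),
        "feat_d": rng.normal(size=n),
        "feat_e": rng.normal(size=n),
    })
    red = reduce_features(table)
    assert len(red.retained_) == 4
    log = red.removal_log_.set_index("feature")
    assert log.loc["feat_const", "reason"] == "inactive"
    removed_pair = set(log.index) & {"feat_a", "feat_b"}
    assert len(removed_pair) == 1
    assert log.loc[removed_pair.pop(), "reason"] == "redundant"


def test_exact_duplicate_feature_removed():
    rng = np.random.default_rng(4)
    x = rng.normal(size=200)
    table = pd.DataFrame({"f1": x, "f2": x.copy(), "f3": rng.normal(size=200)})
    red = CorrelationFeatureReducer().fit(table)
    assert len(red.retained_) == 2
    assert (red.removal_log_["reason"] == "redundant").all()


def test_reduction_is_idempotent_and_logs_are_complete():
    spec = MorphSpec(n_cells_per_group=300, n_features=40, n_inactive=4,
                     corr_blocks=((5, 0.95), (3, 0.9)))
    table, _ = datasets.make_morphology(spec, seed=2)
    normed, _ = robust_z_reference(table)
    red = reduce_features(normed)
    # completeness: retained + removed == input
    assert (set(red.retained_) | set(red.removal_log_["feature"])
            == set(red.feature_names_in_))
    assert len(red.retained_) + len(red.removal_log_) == 40
    # no retained pair above the cut
    reduced = red.transform(normed)
    corr = np.abs(np.corrcoef(reduced[red.retained_].to_numpy().T))
    np.fill_diagonal(corr, 0.0)
    assert corr.max() <= 0.85
    # idempotence
    again = reduce_features(reduced)
    assert len(again.removal_log_) == 0
    assert again.retained_ == red.retained_


def test_reduction_hits_planted_retained_count():
    # 148 features: 10 inactive + 6 blocks of 14 (13 dropped each) -> 60 kept
    spec = MorphSpec(n_cells_per_group=300, n_features=148, n_inactive=10,
                     corr_blocks=tuple((14, 0.95) for _ in range(6)))
    table, _ = datasets.make_morphology(spec, seed=8)
    normed, _ = robust_z_reference(table)
    red = reduce_features(normed)
    assert len(red.retained_) == 60
    reasons = red.removal_log_["reason"].value_counts()
    assert reasons["inactive"] == 10
    assert reasons["redundant"] == 78


def test_all_features_removed_is_an_error():
    table = pd.DataFrame({"f1": np.zeros(50), "f2": np.zeros(50)})
    with pytest.raises(ValueError, match="all features removed"):
        CorrelationFeatureReducer().fit(table)


def test_null_feature_tests_are_calibrated():
    spec = MorphSpec(n_cells_per_group=500, n_features=50, n_inactive=0,
                     group_shift=0.0)
    table, _ = datasets.make_morphology(spec, seed=5)
    normed, _ = robust_z_reference(table)
    res = run_feature_tests(normed, "negative", "positive")
    frac = float((res["p_value"] < 0.05).mean())
    assert 0.01 <= frac <= 0.10
    assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()


def test_shifted_features_are_detected():
    spec = MorphSpec(n_cells_per_group=500, n_features=10, n_inactive=0,
                     group_shift=1.0)
    table, _ = datasets.make_morphology(spec, seed=6)
    normed, _ = robust_z_reference(table)
    res = run_feature_tests(normed, "negative", "positive")
    assert (res["p_value"] < 1e-6).all()


def test_label_permutation_centres_the_statistics():
    spec = MorphSpec(n_cells_per_group=400, n_features=30, n_inactive=0,
                     group_shift=1.0)
    table, _ = datasets.make_morphology(spec, seed=9)
    rng = np.random.default_rng(10)
    permuted = table.copy()
    permuted["group"] = rng.permutation(permuted["group"].to_numpy())
    res = run_feature_tests(permuted, "negative", "positive")
    assert abs(res["statistic"].mean()) < 0.5


def test_degenerate_feature_reported_with_p_one():
    table = pd.DataFrame({
        "group": ["a"] * 5 + ["b"] * 5,
        "flat": np.zeros(10),
        "ok": np.arange(10.0),
    })
    res = run_feature_tests(table, "a", "b").set_index("feature")
    assert res.loc["flat", "degenerate"]
    assert res.loc["flat", "p_value"] == 1.0
    with pytest.raises(ValueError):
        run_feature_tests(table.iloc[:6], "a", "b")
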