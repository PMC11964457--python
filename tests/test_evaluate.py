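import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import precision_recall_fscore_support

import pdgait as pg
from pdgait.augment import AugmentationConfig
from pdgait.errors import DegenerateInputWarning
from pdgait.evaluate import (
    augmentation_effect_ttest,
    classification_metrics,
    compare_augmentations,
    comparison_table,
    cross_validate,
    sensor_ablation,
)
from pdgait.models import ConvNetConfig, TrainConfig

# ------------------------------------------------------------------ metrics


def test_worked_binary_example():
    # TP=3, FP=1, FN=1, TN=2 with class 1 as positive
    cm = np.array([[2, 1], [1, 3]])
    m = classification_metrics(cm)
    pos = m["per_class"][1]
    assert pos["precision"] == pytest.approx(0.75)
    assert pos["recall"] == pytest.approx(0.75)
    assert pos["f1"] == pytest.approx(0.75)
    assert m["accuracy"] == pytest.approx(5 / 7)


def test_perfect_confusion_matrix():
    m = classification_metrics(np.diag([5, 3, 2, 4]))
    assert m["accuracy"] == 1.0
    for c in m["per_class"]:
        assert c["precision"] == c["recall"] == c["f1"] == 1.0


def test_equal_supports_weighted_equals_unweighted_mean(rng):
    cm = rng.integers(1, 9, (4, 4))
    cm = (cm * (10.0 / cm.sum(axis=1, keepdims=True))).round().astype(int)
    cm[:, 0] += 10 - cm.sum(axis=1)  # force equal supports of 10
    m = classification_metrics(cm)
    for name in ("precision", "recall", "f1"):
        unweighted = np.mean([c[name] for c in m["per_class"]])
        assert m["weighted"][name] == pytest.approx(unweighted)


def test_metrics_match_sklearn_recount_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(10, 1000))
        y_true = rng.integers(0, 4, n)
        y_pred = rng.integers(0, 4, n)
        cm = sk_confusion(y_true, y_pred, labels=range(4))
        with np.errstate(all="ignore"):
            m = classification_metrics(cm)
        p, r, f, s = precision_recall_fscore_support(
            y_true, y_pred, labels=range(4), zero_division=0
        )
        for ci in range(4):
            assert m["per_class"][ci]["precision"] == pytest.approx(p[ci], abs=1e-12)
            assert m["per_class"][ci]["recall"] == pytest.approx(r[ci], abs=1e-12)
            assert m["per_class"][ci]["f1"] == pytest.approx(f[ci], abs=1e-12)
        assert m["accuracy"] == pytest.approx(np.mean(y_true == y_pred), abs=1e-12)


def test_zero_denominator_defined_as_zero():
    cm = np.array([[5, 0], [0, 0]])  # class 1 never occurs nor is predicted
    with pytest.warns(DegenerateInputWarning):
        m = classification_metrics(cm)
    assert m["per_class"][1]["precision"] == 0.0


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        classification_metrics(np.zeros((0, 0)))


# ------------------------------------------------------------------ t-test


def _welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    from scipy.stats import t as tdist

    return t, df, 2 * tdist.sf(abs(t), df)


def test_ttest_identical_samples_p_is_one():
    res = augmentation_effect_ttest([1, 1, 1], [1, 1, 1])
    assert res.p == 1.0


def test_ttest_separated_samples_small_p():
    a = np.array([0.0, 0.0, 0.0, 0.0]) + np.array([-0.01, 0.01, -0.01, 0.01])
    b = np.array([1.0, 1.0, 1.0, 1.0]) + np.array([0.01, -0.01, 0.01, -0.01])
    res = augmentation_effect_ttest(a, b)
    t0, df0, p0 = _welch_oracle(a, b)
    assert res.p < 0.01
    assert res.t == pytest.approx(t0, abs=1e-10)
    assert res.df == pytest.approx(df0, abs=1e-10)
    assert res.p == pytest.approx(p0, abs=1e-10)


def test_ttest_antisymmetric_in_sample_order(rng):
    a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
    r1 = augmentation_effect_ttest(a, b)
    r2 = augmentation_effect_ttest(b, a)
    assert r1.t == pytest.approx(-r2.t)
    assert r1.p == pytest.approx(r2.p)


def test_ttest_needs_two_per_sample():
    with pytest.raises(ValueError):
        augmentation_effect_ttest([1.0], [1.0, 2.0])


# ---------------------------------------------------------------- cross-validation

_FAST_CONV = ConvNetConfig(conv_specs=((4, 3), (8, 3), (8, 3), (1, 3)),
                           fusion=(32, 12), dense_per_channel=8, batch_size=100)
_FAST_TRAIN = TrainConfig(max_epochs=3, patience=3, learning_rate=1e-3)


@pytest.fixture(scope="module")
def tiny_cohort():
    return pg.simulate_cohort(pg.GaitSimConfig(n_subjects_per_class=2, duration=6.0, seed=21))


def test_cross_validate_plumbing(tiny_cohort):
    rep = cross_validate(tiny_cohort, _FAST_CONV, None, k=2, seed=5,
                         train_config=_FAST_TRAIN)
    assert rep.confusion.shape == (4, 4)
    assert rep.confusion.sum() == len(tiny_cohort.walks)
    assert 0.0 <= rep.accuracy <= 1.0
    assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / rep.confusion.sum())
    assert len(rep.fold_accuracies) == 2


def test_cross_validate_reproducible(tiny_cohort):
    r1 = cross_validate(tiny_cohort, _FAST_CONV, None, k=2, seed=5, train_config=_FAST_TRAIN)
    r2 = cross_validate(tiny_cohort, _FAST_CONV, None, k=2, seed=5, train_config=_FAST_TRAIN)
    assert np.array_equal(r1.confusion, r2.confusion)
    assert r1.metadata["fold_manifest_hash"] == r2.metadata["fold_manifest_hash"]


def test_compare_augmentations_shares_fold_manifests(tiny_cohort):
    reports = compare_augmentations(
        tiny_cohort,
        {"none": None, "jitter": AugmentationConfig(operators=("jitter",))},
        _FAST_CONV, k=2, seed=5, train_config=_FAST_TRAIN,
    )
    hashes = {r.metadata["fold_manifest_hash"] for r in reports.values()}
    assert len(hashes) == 1
    table = comparison_table(reports)
    assert set(table.columns) >= {"metric", "label", "none", "jitter"}
    assert len(table) == 3 * 5 + 1  # 3 metrics x (4 classes + weighted avg) + accuracy


def test_sensor_ablation_reduces_channels_and_ranks(tiny_cohort):
    table, reports = sensor_ablation(tiny_cohort, _FAST_CONV, ["L1&R1", "TotalL&TotalR"],
                                     k=2, seed=5, train_config=_FAST_TRAIN)
    assert list(table.columns) == ["pair", "precision", "recall", "f1", "accuracy"]
    assert len(table) == 2
    assert table["accuracy"].is_monotonic_increasing
    with pytest.raises(ValueError):
        sensor_ablation(tiny_cohort, _FAST_CONV, ["L9&R9"], k=2, seed=5)


def test_walk_results_pool_over_folds(tiny_cohort):
    rep = cross_validate(tiny_cohort, _FAST_CONV, None, k=2, seed=5, train_config=_FAST_TRAIN)
    assert len(rep.walk_results) == len(tiny_cohort.walks)
    assert set(rep.correctness) <= {0, 1}
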