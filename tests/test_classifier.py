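"""Feed-forward classifier, confusion metrics, AUC and the testing protocols."""

import numpy as np
import pytest

from conftest import planted_classification
from osteomap.classifier import (
    ArmMetrics,
    TrainConfig,
    ab_ba_protocol,
    confusion_metrics,
    evaluate,
    pool_arms,
    train_mlp,
    tripartite_protocol,
)

FAST = TrainConfig(epochs=120, learning_rate=0.02, seed=0)


def test_separable_data_trains_to_full_accuracy():
    X, y = planted_classification(0, n=200, sep=6.0)
    model = train_mlp(X, y, FAST)
    assert evaluate(model, X, y).accuracy == 100.0


def test_training_loss_decreases():
    X, y = planted_classification(1, n=200, sep=2.0)
    model = train_mlp(X, y, FAST)
    assert model.loss_curve[-1] < model.loss_curve[0]


def test_fixed_seed_identical_weights():
    X, y = planted_classification(2, n=150)
    m1 = train_mlp(X, y, FAST)
    m2 = train_mlp(X, y, FAST)
    for a, b in zip(m1.estimator.coefs_, m2.estimator.coefs_):
        np.testing.assert_array_equal(a, b)


def test_permuted_labels_test_accuracy_near_chance():
    accs = []
    for seed in range(10):
        X, y = planted_classification(seed, n=300, sep=3.0)
        y_perm = np.random.default_rng(500 + seed).permutation(y)
        half = len(y) // 2
        model = train_mlp(X[:half], y_perm[:half],
                          TrainConfig(epochs=120, seed=seed))
        accs.append(evaluate(model, X[half:], y_perm[half:]).accuracy / 100.0)
    assert abs(np.mean(accs) - 0.5) < 0.05  # balanced classes: prevalence 0.5


def test_single_class_training_rejected():
    X = np.random.default_rng(0).random((10, 3))
    with pytest.raises(ValueError, match="both outcome classes"):
        train_mlp(X, np.zeros(10, int), FAST)


# ------------------------------------------------------------ metrics


def test_hand_confusion_matrix():
    """TP=3 FN=1 TN=4 FP=2 -> sens 75.00, spec 66.67, acc 70.00."""
    y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    y_pred = [1, 1, 1, 0, 0, 0, 0, 0, 1, 1]
    m = confusion_metrics(y_true, y_pred)
    assert round(m.sensitivity, 2) == 75.00
    assert round(m.specificity, 2) == 66.67
    assert round(m.accuracy, 2) == 70.00


def test_all_correct_predictions():
    y = [1, 1, 0, 0]
    m = confusion_metrics(y, y, scores=[0.9, 0.8, 0.1, 0.2])
    assert (m.sensitivity, m.specificity, m.accuracy, m.auc) == (100.0, 100.0, 100.0, 1.0)


def test_constant_scores_auc_half():
    m = confusion_metrics([1, 0, 1, 0], [1, 1, 1, 1], scores=[0.7] * 4)
    assert m.auc == pytest.approx(0.5)


def test_auc_matches_brute_force_pair_count():
    """Rank AUC equals the positive-negative pair statistic with ties halved."""
    rng = np.random.default_rng(12)
    y = rng.integers(0, 2, size=50)
    y[:2] = [0, 1]  # both classes present
    scores = np.round(rng.random(50), 1)  # coarse grid forces ties
    m = confusion_metrics(y, (scores > 0.5).astype(int), scores=scores)
    pos, neg = scores[y == 1], scores[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    assert m.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


def test_one_class_test_set_flagged():
    m = confusion_metrics([1, 1, 1], [1, 0, 1], scores=[0.9, 0.2, 0.8])
    assert m.auc is None and "single-class" in m.flag


def test_accuracy_identity_with_class_counts():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 80)
    y[:2] = [0, 1]
    pred = rng.integers(0, 2, 80)
    m = confusion_metrics(y, pred)
    recon = (m.sensitivity * m.n_pos + m.specificity * m.n_neg) / m.records
    assert m.accuracy == pytest.approx(recon, abs=1e-9)


# ------------------------------------------------------------ pooling


def _arm(sens, spec, acc, auc, records=50, n_pos=20):
    return ArmMetrics(records=records, n_pos=n_pos, n_neg=records - n_pos,
                      sensitivity=sens, specificity=spec, accuracy=acc, auc=auc)


def test_pooling_is_unweighted_mean():
    pooled = pool_arms([_arm(80.0, 70.0, 75.0, 0.8), _arm(60.0, 90.0, 77.0, 0.7)])
    assert pooled.sensitivity == pytest.approx(70.0)
    assert pooled.accuracy == pytest.approx(76.0)
    assert pooled.auc == pytest.approx(0.75)
    assert pooled.records == 100 and pooled.n_pos == 40


def test_identical_arms_pool_to_themselves():
    arm = _arm(81.5, 72.5, 77.0, 0.81)
    pooled = pool_arms([arm, arm])
    assert (pooled.sensitivity, pooled.specificity, pooled.accuracy, pooled.auc) == (
        arm.sensitivity, arm.specificity, arm.accuracy, arm.auc)


# ------------------------------------------------------------ protocols


def test_ab_ba_pooled_equals_mean_of_arms():
    X, y = planted_classification(4, n=200, sep=2.0)
    half = len(y) // 2
    ab, ba, pooled = ab_ba_protocol(X[:half], y[:half], X[half:], y[half:], FAST)
    assert pooled.accuracy == pytest.approx((ab.accuracy + ba.accuracy) / 2)
    assert pooled.sensitivity == pytest.approx((ab.sensitivity + ba.sensitivity) / 2)


def test_tripartite_runs_with_published_subset_sizes():
    X, y = planted_classification(5, n=174, sep=2.0)
    split = {"train": np.arange(64), "test": np.arange(64, 124),
             "validation": np.arange(124, 174)}
    table = tripartite_protocol(X, y, split, FAST)
    assert list(table.index) == ["sequence AB", "sequence BA", "validation"]
    assert table.loc["validation", "records"] == 50


def test_tripartite_rejects_overlap():
    X, y = planted_classification(6, n=60, sep=2.0)
    split = {"train": np.arange(20), "test": np.arange(20, 40),
             "validation": np.arange(15, 60)}
    with pytest.raises(ValueError, match="overlap"):
        tripartite_protocol(X, y, split, FAST)


def test_tripartite_rejects_validation_equal_to_training():
    X, y = planted_classification(7, n=40, sep=2.0)
    split = {"train": np.arange(20), "test": np.arange(20, 40),
             "validation": np.arange(20)}
    with pytest.raises(ValueError, match="overlap"):
        tripartite_protocol(X, y, split, FAST)


def test_tripartite_separable_validation_accuracy():
    X, y = planted_classification(8, n=174, sep=6.0)
    split = {"train": np.arange(64), "test": np.arange(64, 124),
             "validation": np.arange(124, 174)}
    table = tripartite_protocol(X, y, split, FAST)
    assert table.loc["validation", "accuracy_pct"] > 95.0
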