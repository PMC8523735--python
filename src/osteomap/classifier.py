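"""Supervised feed-forward classifier with two-arm and tripartite protocols.

The predictive model is a standard feed-forward back-propagation network
``y = f(x, w*)``: one hidden layer of logistic units (width defaulting to
the number of input variables), trained to discriminate incident-fracture
from non-fracture records.  Evaluation follows the cross-testing protocols
used for small clinical cohorts:

* **A-B / B-A**: the cohort is split into subsets A and B; one arm trains
  on A and tests on B, the other the reverse; per-arm sensitivity,
  specificity, overall accuracy (percent) and AUC are pooled as their
  unweighted arithmetic means, record and class counts as sums.
* **Tripartite**: two subsets drive the A-B/B-A arms; a third, held-out
  subset is scored by a model trained on the union of the first two and
  never exposed to it.

The network itself is `sklearn`'s multilayer perceptron; this module owns
the protocol logic, metric definitions and pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier

__all__ = [
    "TrainConfig",
    "MLPModel",
    "ArmMetrics",
    "PooledMetrics",
    "train_mlp",
    "evaluate",
    "pool_arms",
    "ab_ba_protocol",
    "tripartite_protocol",
]


@dataclass(frozen=True)
class TrainConfig:
    """Feed-forward network training settings."""

    hidden: int | None = None  # None -> number of input variables
    epochs: int = 500
    learning_rate: float = 0.01
    seed: int = 0
    tol: float = 0.0  # run the full epoch budget by default


@dataclass
class MLPModel:
    """Trained network plus its configuration and training loss trace."""

    estimator: MLPClassifier
    config: TrainConfig
    loss_curve: list[float]
    n_features: int

    def predict_proba(self, X) -> np.ndarray:
        """Positive-class probability per record."""
        X = np.asarray(X, dtype=float)
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


@dataclass
class ArmMetrics:
    """Confusion-matrix metrics of one testing arm (percentages)."""

    records: int
    n_pos: int
    n_neg: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None
    flag: str = ""

    def to_dict(self) -> dict:
        return {
            "records": self.records,
            "fracture_yes": self.n_pos,
            "fracture_no": self.n_neg,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
            "auc": self.auc,
        }


@dataclass
class PooledMetrics:
    """Unweighted means of arm metrics; counts are summed."""

    records: int
    n_pos: int
    n_neg: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None

    def to_dict(self) -> dict:
        return {
            "records": self.records,
            "fracture_yes": self.n_pos,
            "fracture_no": self.n_neg,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
            "auc": self.auc,
        }


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2D with one row per label")
    return X, y


def train_mlp(X, y, config: TrainConfig | None = None) -> MLPModel:
    """Train the feed-forward network; deterministic for a fixed seed."""
    config = config or TrainConfig()
    X, y = _check_xy(X, y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set must contain both outcome classes")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 records per class to train")
    hidden = config.hidden if config.hidden is not None else X.shape[1]
    est = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        tol=config.tol,
        n_iter_no_change=config.epochs,  # early stopping off
        random_state=config.seed % (2**31),
        shuffle=True,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        est.fit(X, y)
    return MLPModel(
        estimator=est,
        config=config,
        loss_curve=list(est.loss_curve_),
        n_features=X.shape[1],
    )


def confusion_metrics(y_true, y_pred, scores=None) -> ArmMetrics:
    """Sensitivity/specificity/accuracy (percent) and rank-based AUC."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("empty test set")
    flag = ""
    sens = 100.0 * tp / n_pos if n_pos else np.nan
    spec = 100.0 * tn / n_neg if n_neg else np.nan
    if n_pos == 0 or n_neg == 0:
        flag = "single-class test set: AUC and one of sens/spec undefined"
        auc = None
    elif scores is None:
        auc = None
    else:
        auc = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    return ArmMetrics(
        records=n,
        n_pos=n_pos,
        n_neg=n_neg,
        sensitivity=sens,
        specificity=spec,
        accuracy=100.0 * (tp + tn) / n,
        auc=auc,
        flag=flag,
    )


def evaluate(model: MLPModel, X, y, threshold: float = 0.5) -> ArmMetrics:
    """Score a test set with a trained model (0.5 probability threshold)."""
    X, y = _check_xy(X, y)
    scores = model.predict_proba(X)
    return confusion_metrics(y, (scores >= threshold).astype(int), scores)


def pool_arms(arms: list[ArmMetrics]) -> PooledMetrics:
    """Unweighted arithmetic mean of arm metrics; counts summed."""
    if not arms:
        raise ValueError("no arms to pool")
    aucs = [a.auc for a in arms]
    return PooledMetrics(
        records=sum(a.records for a in arms),
        n_pos=sum(a.n_pos for a in arms),
        n_neg=sum(a.n_neg for a in arms),
        sensitivity=float(np.mean([a.sensitivity for a in arms])),
        specificity=float(np.mean([a.specificity for a in arms])),
        accuracy=float(np.mean([a.accuracy for a in arms])),
        auc=None if any(a is None for a in aucs) else float(np.mean(aucs)),
    )


def ab_ba_protocol(
    XA,
    yA,
    XB,
    yB,
    config: TrainConfig | None = None,
) -> tuple[ArmMetrics, ArmMetrics, PooledMetrics]:
    """Train-on-A/test-on-B, the reverse, and the pooled row."""
    config = config or TrainConfig()
    model_ab = train_mlp(XA, yA, config)
    arm_ab = evaluate(model_ab, XB, yB)
    model_ba = train_mlp(XB, yB, replace(config, seed=config.seed + 1))
    arm_ba = evaluate(model_ba, XA, yA)
    return arm_ab, arm_ba, pool_arms([arm_ab, arm_ba])


def tripartite_protocol(
    X,
    y,
    split: dict[str, np.ndarray],
    config: TrainConfig | None = None,
) -> pd.DataFrame:
    """A-B/B-A on two subsets plus a held-out validation subset.

    ``split`` maps 'train', 'test', 'validation' to disjoint index arrays.
    The validation row comes from a model trained on train+test records
    only, so validation records are never seen during training.
    """
    config = config or TrainConfig()
    X, y = _check_xy(X, y)
    required = ("train", "test", "validation")
    if set(split) != set(required):
        raise ValueError(f"split must define exactly {required}")
    idx = {k: np.asarray(v, dtype=int) for k, v in split.items()}
    for k, v in idx.items():
        if len(v) == 0:
            raise ValueError(f"subset {k!r} is empty")
    for a in range(len(required)):
        for b in range(a + 1, len(required)):
            if np.intersect1d(idx[required[a]], idx[required[b]]).size:
                raise ValueError(
                    f"subsets {required[a]!r} and {required[b]!r} overlap"
                )

    i1, i2, i3 = idx["train"], idx["test"], idx["validation"]
    arm_ab, arm_ba, _ = ab_ba_protocol(X[i1], y[i1], X[i2], y[i2], config)
    i12 = np.concatenate([i1, i2])
    model_val = train_mlp(X[i12], y[i12], replace(config, seed=config.seed + 2))
    arm_val = evaluate(model_val, X[i3], y[i3])
    rows = {
        "sequence AB": arm_ab.to_dict(),
        "sequence BA": arm_ba.to_dict(),
        "validation": arm_val.to_dict(),
    }
    return pd.DataFrame(rows).T
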