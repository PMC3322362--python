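"""Cross-validation and performance metrics.

Metrics follow the usual confusion-matrix definitions
(precision = TP/(TP+FP), recall = TP/(TP+FN),
accuracy = (TP+TN)/total, F = harmonic mean of precision and recall);
a zero-denominator metric is reported as None (undefined), never as 0.
ROC/AUC uses the trapezoidal integral of the ROC curve, which equals the
Mann-Whitney concordance probability with ties counted one half.

Cross-validation is stratified over pairs with a seeded shuffle, and the
confusion counts are pooled (micro-averaged) over the held-out folds.
Splits are over pairs, not sequences: a protein or RNA occurring in
several pairs may appear on both sides of a split, a known source of
optimistic bias when the question is generalization to unseen molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from . import encoding
from .models import ModelConfig, classify, predict_proba, train
from .sequences import PairDataset


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.TN + other.TN,
            self.FN + other.FN,
        )

    @staticmethod
    def from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return ConfusionCounts(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def compute_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Precision, recall, accuracy and F-measure from confusion counts.

    Metrics with a zero denominator come back as None.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    precision = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else None
    recall = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else None
    accuracy = (counts.TP + counts.TN) / counts.total
    if precision is None or recall is None or precision + recall == 0:
        f_measure = None
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "accuracy": accuracy,
        "f_measure": f_measure,
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC plus the ROC polyline as an array of (FPR, TPR) rows.

    The trapezoidal integral of the returned curve equals the
    Mann-Whitney concordance probability with ties counted 1/2.  The
    curve starts at (0, 0) and ends at (1, 1), ordered by decreasing
    score threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist()) & {0, 1}) < 2:
        raise ValueError("ROC needs both a positive and a negative class")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


@dataclass
class EvaluationReport:
    counts: ConfusionCounts
    metrics: dict[str, float | None]
    auc: float
    roc_points: np.ndarray = field(repr=False)
    fold_counts: list[ConfusionCounts] = field(default_factory=list)
    scores: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict[str, object]:
        return {
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "TN": self.counts.TN,
            "FN": self.counts.FN,
            **self.metrics,
            "auc": self.auc,
            "n_folds": len(self.fold_counts),
        }


def _held_out_scores(
    X: np.ndarray, y: np.ndarray, config: ModelConfig, splits
) -> tuple[np.ndarray, list[ConfusionCounts]]:
    scores = np.full(len(y), np.nan)
    fold_counts: list[ConfusionCounts] = []
    for train_idx, test_idx in splits:
        model = train(None, config, X=X[train_idx], y=y[train_idx])
        p = predict_proba(model, X[test_idx])
        scores[test_idx] = p
        fold_counts.append(
            ConfusionCounts.from_predictions(
                y[test_idx], classify(p, config.decision_threshold)
            )
        )
    assert not np.any(np.isnan(scores)), "every pair must be scored exactly once"
    return scores, fold_counts


def cross_validate(
    dataset: PairDataset | None,
    config: ModelConfig | None = None,
    folds: int = 10,
    seed: int | None = None,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with pooled confusion counts.

    Each pair is scored exactly once, while held out; the report's
    metrics come from the pooled counts and the AUC from the pooled
    held-out scores.  Deterministic given the seed (defaults to
    ``config.seed``).
    """
    config = config or ModelConfig()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if X is None or y is None:
        if dataset is None:
            raise ValueError("either a dataset or X and y must be given")
        X, y, _ = encoding.encode_dataset(dataset)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    minority = min(np.sum(y == 1), np.sum(y == 0))
    if folds > minority:
        raise ValueError(
            f"fold count {folds} exceeds minority class size {minority}"
        )
    seed = config.seed if seed is None else seed
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores, fold_counts = _held_out_scores(X, y, config, cv.split(X, y))
    pooled = sum(fold_counts, ConfusionCounts())
    auc, roc_points = roc_auc(scores, y)
    return EvaluationReport(
        counts=pooled,
        metrics=compute_metrics(pooled),
        auc=auc,
        roc_points=roc_points,
        fold_counts=fold_counts,
        scores=scores,
        labels=y,
    )


def leave_one_out(
    dataset: PairDataset | None,
    config: ModelConfig | None = None,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> EvaluationReport:
    """Leave-one-out cross-validation (k = n, unstratified)."""
    config = config or ModelConfig()
    if X is None or y is None:
        if dataset is None:
            raise ValueError("either a dataset or X and y must be given")
        X, y, _ = encoding.encode_dataset(dataset)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 2:
        raise ValueError("leave-one-out requires at least 2 pairs")
    cv = KFold(n_splits=n)
    scores, fold_counts = _held_out_scores(X, y, config, cv.split(X))
    pooled = sum(fold_counts, ConfusionCounts())
    auc, roc_points = roc_auc(scores, y)
    return EvaluationReport(
        counts=pooled,
        metrics=compute_metrics(pooled),
        auc=auc,
        roc_points=roc_points,
        fold_counts=fold_counts,
        scores=scores,
        labels=y,
    )
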