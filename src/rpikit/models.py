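"""Classifiers over 599-feature pair vectors.

Two families are supported:

* a Random Forest (default 20 trees, 10 candidate features per split;
  500 trees for the large-comparison setting) whose interaction
  probability is the fraction of trees voting "interacting", and
* a soft-margin SVM with the normalized polynomial kernel of order 2,
  K(x, y) = (x.y + 1)^2 / sqrt((x.x + 1)^2 (y.y + 1)^2), C = 1.0 and
  tolerance 1e-3, whose margins are mapped to probabilities by a
  logistic (Platt) model fitted on 3-fold cross-validated margins.

Both are deterministic given the configured seed.  A pair is called
"interacting" when its probability reaches the decision threshold
(inclusive; default 0.50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import encoding
from .sequences import PairDataset

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for either classifier family.

    ``rf_features_per_split`` defaults to 10 for the 599-feature pair
    encoding; when set to None the fallback rule
    floor(log2(n_features)) + 1 applies.  ``svm_epsilon`` is the
    round-off epsilon of the SMO formulation; it is recorded for
    provenance but the solver used here does not expose it.
    """

    family: str = "random_forest"  # or "svm"
    rf_trees: int = 20
    rf_features_per_split: int | None = 10
    svm_C: float = 1.0
    svm_tolerance: float = 0.0010
    svm_kernel_degree: int = 2
    svm_epsilon: float = 1.0e-12
    calibrate: bool = True
    seed: int = 0
    decision_threshold: float = 0.50

    def __post_init__(self) -> None:
        if self.family not in ("random_forest", "svm"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")
        if not (0.0 < self.decision_threshold < 1.0):
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.svm_C <= 0 or self.svm_tolerance <= 0 or self.svm_epsilon <= 0:
            raise ValueError("svm_C, svm_tolerance and svm_epsilon must be positive")


def normalized_poly_kernel(x: np.ndarray, y: np.ndarray, degree: int = 2) -> float:
    """Normalized polynomial kernel between two vectors.

    K(x, y) = (x.y + 1)^degree, normalized to
    K(x, y) / sqrt(K(x, x) K(y, y)).  Symmetric; equals 1 at x == y and
    lies in (0, 1] for non-negative feature vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    kxy = (x @ y + 1.0) ** degree
    kxx = (x @ x + 1.0) ** degree
    kyy = (y @ y + 1.0) ** degree
    return kxy / math.sqrt(kxx * kyy)


def _gram(X: np.ndarray, Y: np.ndarray, degree: int) -> np.ndarray:
    """Normalized polynomial Gram matrix between row sets X and Y."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    raw = (X @ Y.T + 1.0) ** degree
    dx = (np.einsum("ij,ij->i", X, X) + 1.0) ** degree
    dy = (np.einsum("ij,ij->i", Y, Y) + 1.0) ** degree
    return raw / np.sqrt(np.outer(dx, dy))


class _GramKernel:
    """Picklable callable computing the normalized polynomial Gram matrix."""

    def __init__(self, degree: int):
        self.degree = degree

    def __call__(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        return _gram(X, Y, self.degree)

    def __eq__(self, other) -> bool:
        return isinstance(other, _GramKernel) and other.degree == self.degree


@dataclass
class TrainedModel:
    """A fitted classifier plus its configuration and feature schema."""

    config: ModelConfig
    feature_schema: list[str]
    estimator: object
    format_version: int = MODEL_FORMAT_VERSION
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_schema)

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature schema mismatch: model expects {self.n_features} "
                f"features, got {X.shape[1]}"
            )
        return X


def _make_estimator(config: ModelConfig, n_features: int):
    if config.family == "random_forest":
        m = config.rf_features_per_split
        if m is None:
            m = int(math.floor(math.log2(n_features))) + 1
        return RandomForestClassifier(
            n_estimators=config.rf_trees,
            max_features=min(m, n_features),
            random_state=config.seed,
        )
    svc = SVC(
        kernel=_GramKernel(config.svm_kernel_degree),
        C=config.svm_C,
        tol=config.svm_tolerance,
    )
    if config.calibrate:
        # Platt scaling on 3-fold internal CV margins; ensemble=False keeps a
        # single SVM refit on all data, so probabilities stay monotone in its
        # margin.
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)
    return svc


def train(
    dataset: PairDataset | None,
    config: ModelConfig | None = None,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    feature_schema: list[str] | None = None,
) -> TrainedModel:
    """Fit a classifier on a labeled dataset (or a pre-encoded X, y).

    ``dataset`` pairs labeled positive become class 1, negative class 0;
    unlabeled pairs are rejected.  Deterministic given ``config.seed``.
    """
    config = config or ModelConfig()
    if X is None or y is None:
        if dataset is None:
            raise ValueError("either a dataset or X and y must be given")
        X, y, index = encoding.encode_dataset(dataset)
        if np.any(y < 0):
            bad = [index[i] for i in np.flatnonzero(y < 0)[:5]]
            raise ValueError(f"training pairs must be labeled; unlabeled: {bad}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    schema = feature_schema or encoding.feature_names()
    if X.shape[1] != len(schema):
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns, schema has {len(schema)}"
        )
    est = _make_estimator(config, X.shape[1])
    est.fit(X, y)
    return TrainedModel(config=config, feature_schema=list(schema), estimator=est)


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Interaction probability per pair vector.

    RF: fraction of trees voting class 1 (exact vote count, not leaf
    frequencies).  SVM: calibrated logistic of the margin, or the 0/1
    decision when the model was trained uncalibrated.
    """
    X = model._check(X)
    est = model.estimator
    if model.config.family == "random_forest":
        votes = np.stack([tree.predict(X) for tree in est.estimators_])
        return votes.mean(axis=0)
    if model.config.calibrate:
        return est.predict_proba(X)[:, list(est.classes_).index(1)]
    return (est.decision_function(X) > 0).astype(float)


def classify(probabilities: np.ndarray, threshold: float = 0.50) -> np.ndarray:
    """Binary call: interacting iff probability >= threshold (inclusive)."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(int)


def predict_pairs(model: TrainedModel, dataset: PairDataset) -> np.ndarray:
    """Convenience: encode a dataset's pairs and return probabilities."""
    X, _, _ = encoding.encode_dataset(dataset)
    return predict_proba(model, X)


def feature_importance(model: TrainedModel) -> list[tuple[str, float]]:
    """Features ranked by mean impurity decrease (Random Forest only).

    Returns all features as (name, importance), importance descending,
    ties broken by schema order.  Constant features get importance 0.
    """
    if model.config.family != "random_forest":
        raise ValueError("feature importance requires a random_forest model")
    imp = model.estimator.feature_importances_
    order = sorted(range(len(imp)), key=lambda i: (-imp[i], i))
    return [(model.feature_schema[i], float(imp[i])) for i in order]


def greedy_forward_select(
    dataset: PairDataset | None,
    config: ModelConfig | None = None,
    max_features: int = 10,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    candidate_features: list[int] | None = None,
    cv_folds: int = 3,
) -> tuple[list[int], list[float]]:
    """Greedy forward feature selection with a cross-validated RF evaluator.

    At each step the candidate feature whose addition maximizes the
    stratified ``cv_folds``-fold CV accuracy of an RF restricted to the
    selected set is added; the search stops at ``max_features`` or when
    no candidate improves the score.  Returns the selected feature
    indices (in selection order) and the score trace.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    config = config or ModelConfig()
    if X is None or y is None:
        if dataset is None:
            raise ValueError("either a dataset or X and y must be given")
        X, y, _ = encoding.encode_dataset(dataset)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    pool = list(candidate_features) if candidate_features is not None else list(
        range(X.shape[1])
    )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=config.seed)

    def score(cols: list[int]) -> float:
        rf = RandomForestClassifier(
            n_estimators=config.rf_trees,
            max_features=min(
                config.rf_features_per_split or len(cols), len(cols)
            ),
            random_state=config.seed,
        )
        return float(cross_val_score(rf, X[:, cols], y, cv=cv).mean())

    selected: list[int] = []
    trace: list[float] = []
    best_so_far = -np.inf
    while len(selected) < max_features and pool:
        scored = [(score(selected + [f]), f) for f in pool]
        best_score, best_feat = max(scored, key=lambda t: (t[0], -t[1]))
        if best_score <= best_so_far:
            break
        selected.append(best_feat)
        pool.remove(best_feat)
        trace.append(best_score)
        best_so_far = best_score
        if best_score >= 1.0:
            break
    return selected, trace


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(
        {
            "format_version": model.format_version,
            "config": model.config,
            "feature_schema": model.feature_schema,
            "estimator": model.estimator,
            "metadata": model.metadata,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted or foreign file
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return TrainedModel(
        config=payload["config"],
        feature_schema=payload["feature_schema"],
        estimator=payload["estimator"],
        format_version=payload["format_version"],
        metadata=payload.get("metadata", {}),
    )
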