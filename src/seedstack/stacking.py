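"""Two-layer stacking ensemble with out-of-fold meta-features.

Training protocol:

1. stratified train/test split (default 4:1) of the full dataset;
2. for each of k stratified folds of the training set, fit every base
   learner on the other k−1 folds and predict the held-out fold, so each
   training sample gets exactly one out-of-fold (OOF) prediction per
   base learner;
3. the OOF predictions form the secondary training set (label mode:
   one column per base learner, one-hot encoded for the meta-learner;
   probability mode: one column per learner × class);
4. the meta-learner is trained on the secondary set, and the base
   learners are refit on the full training set for inference;
5. the meta-learner itself is chosen combinatorially: each candidate is
   scored by stratified cross-validation *on the training split's OOF
   meta-features* (never on the test set), ranked by accuracy with ties
   broken by candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold, train_test_split

from .evaluation import confusion_matrix, classification_metrics
from .tuning import _fit_quiet

__all__ = [
    "StackingSpec",
    "MetaFeatures",
    "StackedModel",
    "split_train_test",
    "out_of_fold_predictions",
    "encode_meta_features",
    "fit_stacking",
    "predict",
    "predict_scores",
    "select_meta_learner",
]


@dataclass
class StackingSpec:
    """Base learners and meta-learner as (name, unfitted estimator) pairs."""

    base_learners: list[tuple[str, object]]
    meta_learner: tuple[str, object]
    k: int = 5
    meta_feature_mode: str = "labels"  # "labels" | "probabilities"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.base_learners) < 2:
            raise ValueError("stacking needs at least 2 base learners")
        if self.k < 2:
            raise ValueError("stacking folds k must be >= 2")
        if self.meta_feature_mode not in ("labels", "probabilities"):
            raise ValueError("meta_feature_mode must be 'labels' or 'probabilities'")


@dataclass
class SplitResult:
    X_train: np.ndarray
    X_test: np.ndarray
    y_train: np.ndarray
    y_test: np.ndarray
    train_indices: np.ndarray
    test_indices: np.ndarray


def split_train_test(X, labels, test_fraction: float = 0.2, seed: int = 0) -> SplitResult:
    """Stratified split; indices into the original row order are retained."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    singletons = classes[counts < 2]
    if singletons.size:
        raise ValueError(f"classes with a single sample cannot be split: {singletons.tolist()}")
    idx = np.arange(len(labels))
    tr, te = train_test_split(idx, test_size=test_fraction, stratify=labels, random_state=seed)
    return SplitResult(X[tr], X[te], labels[tr], labels[te], tr, te)


@dataclass
class MetaFeatures:
    matrix: np.ndarray          # n_train × t (labels) or n_train × t·C (probabilities)
    fold_assignment: np.ndarray
    base_names: list[str]
    classes: np.ndarray
    mode: str


def out_of_fold_predictions(
    base_learners: list[tuple[str, object]],
    X_train,
    y_train,
    k: int = 5,
    mode: str = "labels",
    seed: int = 0,
) -> MetaFeatures:
    """OOF prediction matrix in original training-sample order."""
    X = np.asarray(X_train, float)
    y = np.asarray(y_train)
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = np.full(len(y), -1, dtype=int)
    t = len(base_learners)
    if mode == "labels":
        matrix = np.empty((len(y), t), dtype=object)
    else:
        matrix = np.zeros((len(y), t * len(classes)))
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        fold_assignment[va] = fold
        for j, (name, est) in enumerate(base_learners):
            try:
                model = _fit_quiet(clone(est), X[tr], y[tr])
            except Exception as exc:  # noqa: BLE001 - reported with context
                raise RuntimeError(
                    f"base learner {name!r} failed to fit on fold {fold}: {exc}"
                ) from exc
            if mode == "labels":
                matrix[va, j] = model.predict(X[va])
            else:
                matrix[np.ix_(va, range(j * len(classes), (j + 1) * len(classes)))] = (
                    _class_scores(model, X[va], classes)
                )
    return MetaFeatures(matrix, fold_assignment, [n for n, _ in base_learners], classes, mode)


def _class_scores(model, X, classes) -> np.ndarray:
    """Per-class scores aligned with ``classes`` (probabilities if available)."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        cols = {c: i for i, c in enumerate(model.classes_)}
        out = np.zeros((len(X), len(classes)))
        for j, c in enumerate(classes):
            if c in cols:
                out[:, j] = proba[:, cols[c]]
        return out
    scores = model.decision_function(X)
    if scores.ndim == 1:  # binary margin
        scores = np.column_stack([-scores, scores])
    cols = {c: i for i, c in enumerate(model.classes_)}
    out = np.full((len(X), len(classes)), scores.min())
    for j, c in enumerate(classes):
        if c in cols:
            out[:, j] = scores[:, cols[c]]
    return out


def encode_meta_features(meta: MetaFeatures | np.ndarray, classes=None, mode="labels") -> np.ndarray:
    """Numeric design matrix for the meta-learner (one-hot in label mode)."""
    if isinstance(meta, MetaFeatures):
        matrix, classes, mode = meta.matrix, meta.classes, meta.mode
    else:
        matrix = meta
        if classes is None:
            raise ValueError("classes required when passing a raw matrix")
    if mode == "probabilities":
        return np.asarray(matrix, float)
    classes = np.asarray(classes)
    n, t = matrix.shape
    out = np.zeros((n, t * len(classes)))
    for j in range(t):
        codes = np.searchsorted(classes, matrix[:, j])
        valid = np.isin(matrix[:, j], classes)
        out[np.arange(n)[valid], j * len(classes) + codes[valid]] = 1.0
    return out


@dataclass
class StackedModel:
    spec: StackingSpec
    base_models: list[tuple[str, object]]  # refit on the full training set
    meta_model: object
    classes: np.ndarray
    meta_features: MetaFeatures
    n_fit_samples: dict[str, int] = field(default_factory=dict)


def fit_stacking(spec: StackingSpec, X_train, y_train) -> StackedModel:
    """Train the two-layer stack per the five-step protocol."""
    X = np.asarray(X_train, float)
    y = np.asarray(y_train)
    meta = out_of_fold_predictions(
        spec.base_learners, X, y, k=spec.k, mode=spec.meta_feature_mode, seed=spec.seed
    )
    Z = encode_meta_features(meta)
    meta_name, meta_est = spec.meta_learner
    meta_model = _fit_quiet(clone(meta_est), Z, y)
    refit = []
    n_fit = {}
    for name, est in spec.base_learners:
        refit.append((name, _fit_quiet(clone(est), X, y)))
        n_fit[name] = len(y)
    return StackedModel(spec, refit, meta_model, meta.classes, meta, n_fit)


def _base_prediction_matrix(model: StackedModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    mode = model.spec.meta_feature_mode
    if mode == "labels":
        cols = [m.predict(X) for _, m in model.base_models]
        matrix = np.empty((len(X), len(cols)), dtype=object)
        for j, c in enumerate(cols):
            matrix[:, j] = c
        return encode_meta_features(matrix, model.classes, "labels")
    blocks = [_class_scores(m, X, model.classes) for _, m in model.base_models]
    return np.hstack(blocks)


def predict(model: StackedModel, X) -> np.ndarray:
    """Base predictions → meta-features → meta-learner label."""
    Z = _base_prediction_matrix(model, X)
    return model.meta_model.predict(Z)


def predict_scores(model: StackedModel, X) -> np.ndarray:
    """Meta-learner per-class scores aligned with ``model.classes``."""
    Z = _base_prediction_matrix(model, X)
    return _class_scores(model.meta_model, Z, model.classes)


def select_meta_learner(
    candidates: list[tuple[str, object]],
    spec: StackingSpec,
    X_train,
    y_train,
    seed: int = 0,
    meta: MetaFeatures | None = None,
) -> tuple[pd.DataFrame, tuple[str, object]]:
    """Rank candidate meta-learners by CV accuracy on the OOF meta-features.

    The report has one row per candidate (accuracy, macro precision,
    recall, F1). The winner is the accuracy argmax, earliest candidate on
    ties. The test split plays no role here. ``meta`` may carry
    precomputed OOF meta-features for these base learners.
    """
    if not candidates:
        raise ValueError("need at least one candidate meta-learner")
    X = np.asarray(X_train, float)
    y = np.asarray(y_train)
    if meta is None:
        meta = out_of_fold_predictions(
            spec.base_learners, X, y, k=spec.k, mode=spec.meta_feature_mode, seed=spec.seed
        )
    Z = encode_meta_features(meta)
    classes = meta.classes
    skf = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=seed)
    rows = []
    for name, est in candidates:
        y_pred = np.empty(len(y), dtype=object)
        for tr, va in skf.split(Z, y):
            model = _fit_quiet(clone(est), Z[tr], y[tr])
            y_pred[va] = model.predict(Z[va])
        cm = confusion_matrix(y, y_pred, classes)
        rep = classification_metrics(cm)
        rows.append({
            "meta_learner": name,
            "accuracy": rep.accuracy,
            "precision": rep.macro_precision,
            "recall": rep.macro_recall,
            "f1": rep.macro_f1,
        })
    report = pd.DataFrame(rows)
    best_idx = int(report["accuracy"].idxmax())  # idxmax takes the first max
    return report, candidates[best_idx]
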