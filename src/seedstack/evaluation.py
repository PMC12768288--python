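"""Multiclass evaluation: confusion matrix, one-vs-rest metrics, OvR AUC.

Per-class precision, recall and F1 are the one-vs-rest forms

    precision = TP/(TP+FP),  recall = TP/(TP+FN),
    F1 = 2·precision·recall/(precision+recall)

computed from the confusion-matrix marginals; overall accuracy is
trace/total. Macro summaries are unweighted class means (with balanced
classes macro ≈ weighted). A class whose denominator is zero gets
metric 0 with a warning rather than NaN.

``relative_improvement`` implements the reporting convention
100·(value − reference)/reference rounded to two decimals, used for all
model-to-model comparison percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "classification_metrics",
    "roc_auc_ovr",
    "relative_improvement",
    "evaluate_predictions",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = true class, columns = predicted class
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.classes = np.asarray(self.classes)
        C = len(self.classes)
        if self.counts.shape != (C, C):
            raise ValueError(f"counts must be {C}×{C}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def ovr_marginals(self) -> pd.DataFrame:
        """Per-class one-vs-rest TP/FP/FN/TN."""
        tp = np.diag(self.counts)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return pd.DataFrame({"TP": tp, "FP": fp, "FN": fn, "TN": tn}, index=self.classes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class EvaluationReport:
    accuracy: float
    per_class: pd.DataFrame            # precision/recall/f1 (rows = classes)
    macro_precision: float
    macro_recall: float
    macro_f1: float
    cm: ConfusionMatrix
    per_class_auc: pd.Series | None = None
    macro_auc: float | None = None

    def summary_row(self, name: str) -> dict:
        row = {
            "model": name,
            "accuracy": self.accuracy,
            "precision": self.macro_precision,
            "recall": self.macro_recall,
            "f1": self.macro_f1,
        }
        if self.macro_auc is not None:
            row["macro_auc"] = self.macro_auc
        return row


def confusion_matrix(y_true, y_pred, classes) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.asarray(classes)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        unseen = np.setdiff1d(arr, classes)
        if unseen.size:
            raise ValueError(f"{name} contains labels outside the class set: {unseen.tolist()}")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros(len(num))
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if (~ok).any():
        warnings.warn(f"{what} undefined for {int((~ok).sum())} class(es); reported as 0")
    return out


def classification_metrics(cm: ConfusionMatrix) -> EvaluationReport:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    marg = cm.ovr_marginals()
    tp = marg["TP"].to_numpy(float)
    precision = _safe_div(tp, tp + marg["FP"].to_numpy(float), "precision")
    recall = _safe_div(tp, tp + marg["FN"].to_numpy(float), "recall")
    f1 = np.zeros(len(tp))
    ok = (precision + recall) > 0
    f1[ok] = 2 * precision[ok] * recall[ok] / (precision[ok] + recall[ok])
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1}, index=cm.classes
    )
    return EvaluationReport(
        accuracy=float(np.trace(cm.counts) / cm.total),
        per_class=per_class,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        cm=cm,
    )


def roc_auc_ovr(y_true, scores, classes) -> tuple[pd.Series, float]:
    """Per-class one-vs-rest AUC (midrank ties) and their unweighted mean.

    Classes absent from ``y_true`` get NaN and are excluded from the macro
    mean with a warning.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, float)
    classes = np.asarray(classes)
    if scores.shape != (len(y_true), len(classes)):
        raise ValueError("score matrix must be n_samples × n_classes")
    aucs = []
    for j, c in enumerate(classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c!r} absent (or exclusive) in y_true; AUC undefined")
            aucs.append(np.nan)
        else:
            aucs.append(float(roc_auc_score(pos, scores[:, j])))
    per_class = pd.Series(aucs, index=classes, name="auc")
    macro = float(per_class.dropna().mean()) if per_class.notna().any() else np.nan
    return per_class, macro


def relative_improvement(value: float, reference: float) -> float:
    """Percent improvement of ``value`` over ``reference``, two decimals."""
    if reference <= 0:
        raise ValueError("reference score must be > 0")
    return round(100.0 * (value - reference) / reference, 2)


def evaluate_predictions(
    y_true, y_pred, classes, scores: np.ndarray | None = None
) -> EvaluationReport:
    """Convenience wrapper: confusion matrix → metrics (→ AUC if scored)."""
    cm = confusion_matrix(y_true, y_pred, classes)
    report = classification_metrics(cm)
    if scores is not None:
        report.per_class_auc, report.macro_auc = roc_auc_ovr(y_true, scores, classes)
    return report
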