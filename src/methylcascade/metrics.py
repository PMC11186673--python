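"""Evaluation-metric suite: confusion matrices, accuracy, per-class
precision/recall/F1, Matthews correlation coefficient, ROC/PR AUC and
one-vs-all multiclass AUCs.

Conventions (fixed and documented):

* precision, recall, F1 and MCC are 0 whenever their denominator is 0;
* multiclass MCC is the covariance-form generalization over the full
  confusion matrix, which reduces to the familiar
  (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) for two classes;
* ROC AUC is the Mann-Whitney tie-corrected probability statistic;
* PR AUC is the step-wise (interpolation-free) average-precision estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix as _sk_confusion,
    roc_auc_score,
)


class MetricsError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """Class-by-class counts; rows are truth, columns predictions."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.class_names)
        if self.counts.shape != (n, n):
            raise MetricsError("confusion counts must be class x class")
        if (self.counts < 0).any():
            raise MetricsError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)


def confusion(truth, predicted, class_names: list[str]) -> ConfusionMatrix:
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise MetricsError("truth and prediction lengths differ")
    known = set(class_names)
    stray = (set(truth) | set(predicted)) - known
    if stray:
        raise MetricsError(f"labels outside class_names: {stray}")
    counts = _sk_confusion(truth, predicted, labels=class_names)
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def precision_recall(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-class precision and recall with the 0/0 -> 0 convention."""
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    pred_tot = counts.sum(axis=0)
    true_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
    return precision, recall


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    precision = float(precision)
    recall = float(recall)
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise MetricsError(f"{name} must lie in [0, 1], got {v}")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; covariance form for >2 classes,
    exactly the 2x2 formula for binary, 0 when any denominator factor is 0."""
    if cm.total == 0:
        raise MetricsError("empty confusion matrix")
    counts = cm.counts.astype(float)
    s = counts.sum()
    c = np.trace(counts)
    t = counts.sum(axis=1)  # true counts per class
    p = counts.sum(axis=0)  # predicted counts per class
    cov_tp = c * s - t @ p
    cov_tt = s * s - t @ t
    cov_pp = s * s - p @ p
    denom = np.sqrt(cov_tt * cov_pp)
    if denom == 0.0:
        return 0.0
    return float(cov_tp / denom)


def roc_auc(truth, scores) -> float:
    """Binary ROC AUC (tie-corrected Mann-Whitney statistic).  ``truth`` holds
    0/1 or booleans; requires both classes present."""
    y = np.asarray(truth).astype(int)
    if len(np.unique(y)) < 2:
        raise MetricsError("ROC AUC undefined with a single class present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def pr_auc(truth, scores) -> float:
    """Step-wise precision-recall AUC (average precision)."""
    y = np.asarray(truth).astype(int)
    if len(np.unique(y)) < 2:
        raise MetricsError("PR AUC undefined with a single class present")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def one_vs_all_aucs(truth, probabilities: pd.DataFrame) -> pd.DataFrame:
    """Per-class ROC and PR AUC by binarizing each class against the rest.

    ``probabilities`` is samples x classes with class names as columns.
    Classes absent from ``truth`` get NaN.
    """
    truth = np.asarray(list(truth))
    present = set(np.unique(truth))
    if len(present) < 2:
        raise MetricsError("one-vs-all AUCs need at least 2 classes present")
    rows = []
    for cls in probabilities.columns:
        y = (truth == cls).astype(int)
        if 0 < y.sum() < len(y):
            scores = probabilities[cls].to_numpy(dtype=float)
            rows.append((cls, roc_auc(y, scores), pr_auc(y, scores)))
        else:
            rows.append((cls, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["class", "roc_auc", "pr_auc"]).set_index("class")


@dataclass
class EvaluationReport:
    accuracy: float
    per_class: pd.DataFrame       # precision, recall, f1 indexed by class
    mcc: float
    aucs: pd.DataFrame | None     # roc_auc, pr_auc indexed by class
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "per_class": {c: {k: float(v) for k, v in row.items()}
                          for c, row in self.per_class.iterrows()},
            "aucs": (None if self.aucs is None else
                     {c: {k: (None if pd.isna(v) else float(v))
                          for k, v in row.items()}
                      for c, row in self.aucs.iterrows()}),
            "confusion": {
                "class_names": self.confusion.class_names,
                "counts": self.confusion.counts.tolist(),
            },
        }

    def to_json(self, path=None, **kwargs) -> str:
        payload = {"schema_version": 1, **self.to_dict()}
        text = json.dumps(payload, indent=2, sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def evaluate_predictions(truth, predicted, class_names: list[str],
                         probabilities: pd.DataFrame | None = None) -> EvaluationReport:
    """Assemble the full metric suite from labels (and optional class
    probabilities, needed for the AUC block)."""
    cm = confusion(truth, predicted, class_names)
    precision, recall = precision_recall(cm)
    per_class = pd.DataFrame({
        "precision": precision,
        "recall": recall,
        "f1": [f1(p, r) for p, r in zip(precision, recall)],
    }, index=class_names)
    aucs = None
    if probabilities is not None:
        aucs = one_vs_all_aucs(truth, probabilities)
    accuracy = float(np.trace(cm.counts) / cm.total)
    return EvaluationReport(accuracy=accuracy, per_class=per_class,
                            mcc=mcc(cm), aucs=aucs, confusion=cm)


def evaluate(model, dataset, split: str = "test") -> EvaluationReport:
    """Evaluate a trained cascade (or boost stage) on one split of a labeled
    dataset; see :func:`methylcascade.cascade.predict`."""
    from .cascade import predict

    mask = dataset.split == split
    if not mask.any():
        raise MetricsError(f"no samples in split {split!r}")
    m = dataset.m_values.loc[:, mask[mask].index]
    probs, labels = predict(model, m)
    truth = dataset.labels.loc[labels.index]
    return evaluate_predictions(truth, labels, list(probs.columns), probs)
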