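"""Binary classification metrics: confusion table, rates, and rank-based AUC.

Undefined quantities (PPV with no positive predictions, specificity or AUC
with a single observed class) are reported as None with a warning rather
than silently coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass
class MetricsReport:
    accuracy: float
    ppv: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    auc: float | None
    confusion: np.ndarray  # rows = true class, cols = predicted class
    n: int = 0
    per_fold: list["MetricsReport"] | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "auc": self.auc,
            "n": self.n,
            "confusion": [[int(v) for v in row] for row in self.confusion],
        }


def confusion_matrix(labels: np.ndarray, preds: np.ndarray) -> np.ndarray:
    """2x2 table, [true][pred]; true negatives at [0][0], true positives at [1][1]."""
    cm = np.zeros((2, 2), dtype=np.int64)
    for t, p in zip(labels, preds):
        cm[int(t), int(p)] += 1
    return cm


def auc_rank(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank statistic: P(score_pos > score_neg) with ties counted half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def compute_metrics(
    labels: np.ndarray,
    predicted_classes: np.ndarray,
    positive_scores: np.ndarray | None = None,
) -> MetricsReport:
    """Accuracy, PPV, recall, specificity, F1 and (if scores given) AUC."""
    labels = np.asarray(labels)
    predicted_classes = np.asarray(predicted_classes)
    if labels.size == 0 or labels.shape != predicted_classes.shape:
        raise ValueError("labels and predictions must be non-empty and aligned")
    cm = confusion_matrix(labels, predicted_classes)
    tn, fp = int(cm[0, 0]), int(cm[0, 1])
    fn, tp = int(cm[1, 0]), int(cm[1, 1])
    n = tn + fp + fn + tp
    accuracy = (tp + tn) / n

    ppv = recall = specificity = f1 = auc = None
    if tp + fp > 0:
        ppv = tp / (tp + fp)
    else:
        warnings.warn("PPV undefined: no positive predictions", stacklevel=2)
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        warnings.warn("recall undefined: no positive labels", stacklevel=2)
    if tn + fp > 0:
        specificity = tn / (tn + fp)
    else:
        warnings.warn("specificity undefined: no negative labels", stacklevel=2)
    if ppv is not None and recall is not None and (ppv + recall) > 0:
        f1 = 2 * ppv * recall / (ppv + recall)
    if positive_scores is not None:
        positive_scores = np.asarray(positive_scores, dtype=np.float64)
        if positive_scores.shape != labels.shape:
            raise ValueError("positive_scores must align with labels")
        try:
            auc = auc_rank(labels, positive_scores)
        except ValueError:
            warnings.warn("AUC undefined: a class is missing", stacklevel=2)
    return MetricsReport(
        accuracy=accuracy,
        ppv=ppv,
        recall=recall,
        specificity=specificity,
        f1=f1,
        auc=auc,
        confusion=cm,
        n=n,
    )
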