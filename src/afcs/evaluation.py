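"""Classification metrics: confusion matrix, accuracy/precision/recall/F1,
and categorical cross-entropy.

All metrics derive from the K x K confusion matrix (rows = true class,
columns = predicted class).  Precision/recall/F1 are reported either
macro-averaged (unweighted mean over classes) or weighted by class support;
the weighted-recall/accuracy identity holds exactly on every matrix.
Cross-entropy is the mean negative log-probability of the true class, in
nats, with predictions clipped to ``[EPS, 1]`` before the log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = [
    "EPS",
    "MetricsReport",
    "confusion_matrix",
    "classification_metrics",
    "categorical_crossentropy",
]

EPS = 1e-7  # log clipping floor


@dataclass(frozen=True)
class MetricsReport:
    """Scalar classification metrics, all fractions in [0, 1].

    ``loss`` is mean categorical cross-entropy in nats (NaN when no
    probabilistic predictions were available, e.g. for scripted trainers).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    loss: float = float("nan")
    averaging: str = "weighted"

    def as_dict(self) -> dict[str, float | str]:
        return {
            "accuracy": self.accuracy,
            "loss": self.loss,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "averaging": self.averaging,
        }


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Tally ``counts[i, j] = #{true == i and pred == j}`` for labels 0..K-1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for arr, which in ((y_true, "true"), (y_pred, "predicted")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{which} labels outside [0, {n_classes - 1}]")
    return _sk_confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))


def classification_metrics(
    cm: np.ndarray, averaging: str = "weighted"
) -> MetricsReport:
    """Accuracy, precision, recall and F1 from a confusion matrix.

    Per-class precision divides by the column sum and recall by the row
    sum; a class never predicted (zero column) contributes precision 0
    rather than a division error, and likewise for recall on an empty row.
    Averages are computed in exact rational arithmetic (the matrix holds
    integer counts), so the classic accuracy = weighted-recall identity
    holds exactly, not just to rounding.
    """
    from fractions import Fraction

    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if not np.allclose(cm, np.rint(cm)) or np.any(cm < 0):
        raise ValueError("confusion matrix must hold non-negative integer counts")
    counts = np.rint(cm).astype(int)
    k = counts.shape[0]
    total = int(counts.sum())
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    diag = [int(counts[i, i]) for i in range(k)]
    colsum = [int(counts[:, i].sum()) for i in range(k)]
    rowsum = [int(counts[i, :].sum()) for i in range(k)]
    precision_k = [
        Fraction(d, c) if c else Fraction(0) for d, c in zip(diag, colsum)
    ]
    recall_k = [Fraction(d, r) if r else Fraction(0) for d, r in zip(diag, rowsum)]
    f1_k = [
        2 * p * r / (p + r) if p + r else Fraction(0)
        for p, r in zip(precision_k, recall_k)
    ]
    if averaging == "macro":
        weights = [Fraction(1, k)] * k
    elif averaging == "weighted":
        weights = [Fraction(r, total) for r in rowsum]
    else:
        raise ValueError(f"averaging must be 'macro' or 'weighted', got {averaging!r}")
    average = lambda vals: float(sum(v * w for v, w in zip(vals, weights)))
    return MetricsReport(
        accuracy=float(Fraction(sum(diag), total)),
        precision=average(precision_k),
        recall=average(recall_k),
        f1=average(f1_k),
        averaging=averaging,
    )


def categorical_crossentropy(predicted, true, tol: float = 1e-5) -> float:
    """Mean ``-log p(true class)`` in nats.

    ``predicted`` is (n, K) row-stochastic; ``true`` is either an (n, K)
    one-hot matrix or an integer label vector of length n.  Probabilities
    are clipped to ``[EPS, 1]`` before the log.
    """
    p = np.asarray(predicted, dtype=float)
    if p.ndim != 2:
        raise ValueError("predicted distributions must be 2-D (n, K)")
    sums = p.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=tol):
        raise ValueError("each predicted distribution must sum to 1")
    true = np.asarray(true)
    if true.ndim == 2:
        if true.shape != p.shape:
            raise ValueError("one-hot matrix shape mismatch")
        labels = true.argmax(axis=1)
    else:
        if true.shape[0] != p.shape[0]:
            raise ValueError("label vector length mismatch")
        labels = true.astype(int)
    p_true = np.clip(p[np.arange(p.shape[0]), labels], EPS, 1.0)
    return float(-np.log(p_true).mean())
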