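"""Precision-recall machinery shared by the injection benchmark and the
expression-linkage evaluator."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve


def auprc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Interpolation-free area under the precision-recall curve.

    Step-wise (average-precision style): sum over thresholds of
    ``(R_n - R_{n-1}) * P_n``.  ``scores`` must be higher for entries more
    likely to be positive (pass ``-p`` for p-values).
    """
    y = np.asarray(y_true, dtype=bool).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError("shapes of labels and scores differ")
    if not y.any():
        raise ValueError("no positive labels")
    return float(average_precision_score(y, s))


def pr_curve(y_true: np.ndarray, scores: np.ndarray):
    """Precision/recall at every threshold (sklearn convention)."""
    y = np.asarray(y_true, dtype=bool).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    precision, recall, thresholds = precision_recall_curve(y, s)
    return precision, recall, thresholds


def precision_recall_at(flags: np.ndarray, y_true: np.ndarray) -> tuple[float, float]:
    """Precision and recall of a hard call set (e.g. padj < 0.05 or |Z| > 2)."""
    f = np.asarray(flags, dtype=bool).ravel()
    y = np.asarray(y_true, dtype=bool).ravel()
    tp = np.sum(f & y)
    precision = tp / f.sum() if f.any() else float("nan")
    recall = tp / y.sum() if y.any() else float("nan")
    return float(precision), float(recall)
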