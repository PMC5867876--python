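"""Multi-class Matthews correlation coefficient in covariance form, plus
companion confusion-matrix metrics.

The MCC here is the correlation between one-hot indicator matrices of the
predicted and true classes:

    MCC = cov(X, Y) / sqrt(cov(X, X) * cov(Y, Y))

with cov(X, Y) = (1/N) * sum_k sum_i (x_ik - xbar_k)(y_ik - ybar_k) over N
classes and n samples. For two classes this reduces exactly to the
classical binary TP/FP/TN/FN formula. The 1/N prefactors cancel in the
ratio. MCC is the preferred score under heavy class imbalance: +1 is
perfect prediction, 0 chance level, -1 total misclassification.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import ParameterError

__all__ = [
    "indicator",
    "mcc",
    "mcc_from_labels",
    "confusion_counts",
    "basic_metrics",
    "per_class_recalls",
]


def indicator(labels, class_order) -> np.ndarray:
    """One-hot encode labels (n x N) in the given class order."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ParameterError("empty label vector")
    class_order = list(class_order)
    lut = {c: j for j, c in enumerate(class_order)}
    out = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        try:
            out[i, lut[lab]] = 1.0
        except KeyError:
            raise ParameterError(f"label {lab!r} not in class_order") from None
    return out


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    # mean-centered column covariance, summed over classes; the 1/N factor
    # cancels in the MCC ratio and is omitted
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    return float((ac * bc).sum())


def mcc(X: np.ndarray, Y: np.ndarray) -> float:
    """Covariance-form MCC of prediction indicators X vs truth indicators Y.

    Returns 0 (with a warning) when either side is constant — e.g. a
    classifier that always predicts one class — which keeps incremental
    selection curves finite.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ParameterError(f"shape mismatch: {X.shape} vs {Y.shape}")
    sxx = _cov(X, X)
    syy = _cov(Y, Y)
    if sxx == 0.0 or syy == 0.0:
        warnings.warn(
            "degenerate MCC denominator (constant prediction or truth); returning 0",
            stacklevel=2,
        )
        return 0.0
    return _cov(X, Y) / np.sqrt(sxx * syy)


def mcc_from_labels(predicted, truth, class_order=None) -> float:
    """MCC directly from label vectors (classes ordered as given or sorted)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if class_order is None:
        class_order = sorted(set(truth.tolist()) | set(predicted.tolist()))
    return mcc(indicator(predicted, class_order), indicator(truth, class_order))


def confusion_counts(predicted, truth, class_order) -> np.ndarray:
    """N x N confusion matrix, truth in rows, prediction in columns."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    n = len(class_order)
    lut = {c: j for j, c in enumerate(class_order)}
    out = np.zeros((n, n), dtype=int)
    for t, p in zip(truth, predicted):
        out[lut[t], lut[p]] += 1
    return out


def basic_metrics(confusion: np.ndarray, positive_index: int = 0):
    """(sensitivity, specificity, accuracy) from a confusion matrix.

    Sensitivity is the recall of the positive class; specificity the recall
    of its complement (pooled over remaining classes); accuracy the trace
    fraction.
    """
    c = np.asarray(confusion, dtype=float)
    if c.size == 0 or c.sum() == 0:
        raise ParameterError("empty confusion matrix")
    pos = positive_index
    tp = c[pos, pos]
    pos_total = c[pos].sum()
    neg_mask = np.ones(len(c), dtype=bool)
    neg_mask[pos] = False
    tn = c[np.ix_(neg_mask, neg_mask)].sum()
    neg_total = c[neg_mask].sum()
    sensitivity = tp / pos_total if pos_total else 0.0
    specificity = tn / neg_total if neg_total else 0.0
    accuracy = np.trace(c) / c.sum()
    return float(sensitivity), float(specificity), float(accuracy)


def per_class_recalls(confusion: np.ndarray, class_order) -> dict:
    """Recall of every class by name (reported alongside MCC, since which
    class is 'positive' is a convention, not a fact of the data)."""
    c = np.asarray(confusion, dtype=float)
    out = {}
    for j, name in enumerate(class_order):
        total = c[j].sum()
        out[name] = float(c[j, j] / total) if total else 0.0
    return out
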