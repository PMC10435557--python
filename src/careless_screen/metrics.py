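"""Binary classification metrics with careless coded as the positive class.

Sensitivity, specificity, balanced accuracy (their mean), precision, F1
and ROC AUC. Metrics whose denominator is empty are reported as NaN
(flagged undefined) rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; positive = careless (label 1).

    Standard layout: rows = actual, columns = predicted (FN = actual
    positive predicted negative, FP = actual negative predicted positive).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must cover at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(a, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(int)


def confusion_counts(predicted, actual) -> ConfusionCounts:
    """Confusion counts from binary predicted and true labels."""
    pred = _as_binary(predicted, "predicted")
    true = _as_binary(actual, "actual")
    if pred.shape != true.shape:
        raise ValueError("predicted and actual must have equal length")
    return ConfusionCounts(
        tp=int(((pred == 1) & (true == 1)).sum()),
        fp=int(((pred == 1) & (true == 0)).sum()),
        tn=int(((pred == 0) & (true == 0)).sum()),
        fn=int(((pred == 0) & (true == 1)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(c: ConfusionCounts, scores=None,
                           actual=None) -> dict[str, float]:
    """Metric dictionary from confusion counts (and optionally ranking
    scores + true labels for AUC).

    Balanced accuracy is the arithmetic mean of sensitivity and
    specificity; F1 is the standard harmonic mean of precision and
    sensitivity (2*P*S/(P+S)). AUC is the trapezoidal area under the ROC
    over all cutoffs of ``scores`` and is NaN when scores are absent or
    only one class is present.
    """
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    prec = _ratio(c.tp, c.tp + c.fp)
    bacc = (sens + spec) / 2.0  # NaN-propagating
    if np.isnan(sens) or np.isnan(prec) or (prec + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    auc = float("nan")
    if scores is not None:
        if actual is None:
            raise ValueError("AUC needs true labels alongside scores")
        true = _as_binary(actual, "actual")
        if 0 < true.sum() < true.size:
            auc = float(roc_auc_score(true, np.asarray(scores, dtype=float)))
    return {"sensitivity": sens, "specificity": spec,
            "balanced_accuracy": bacc, "precision": prec,
            "f1": f1, "auc": auc}


def balanced_accuracy(predicted, actual) -> float:
    """Convenience wrapper: balanced accuracy from binary labels."""
    m = classification_metrics(confusion_counts(predicted, actual))
    return m["balanced_accuracy"]
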