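"""Classification performance metrics and ROC threshold sweeps.

Sensitivity (recall) = TP/(TP+FN) measures the ability to recognise true
buzzes; specificity = TN/(TN+FP) the ability to recognise true non-buzzes;
balanced accuracy is their mean.  The ROC sweep evaluates the recording
labels over decision thresholds 0.5-1.0 in steps of 0.05 (inclusive >=
labelling), and the confidence interval on overall accuracy is the exact
Clopper-Pearson binomial interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta

__all__ = [
    "ConfusionCounts",
    "RocPoint",
    "confusion_metrics",
    "roc_sweep",
    "score_predictions",
    "accuracy_confidence_interval",
    "metrics_report",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.linspace(0.5, 1.0, 11), 2))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    tpr: float
    fpr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.tpr <= 1.0 and 0.0 <= self.fpr <= 1.0):
            raise ValueError("tpr/fpr must lie in [0, 1]")


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, balanced_accuracy) from confusion counts."""
    if c.tp + c.fn == 0:
        raise ValueError("no positive examples: sensitivity undefined")
    if c.tn + c.fp == 0:
        raise ValueError("no negative examples: specificity undefined")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    return sens, spec, (sens + spec) / 2.0


def roc_sweep(
    probabilities: Sequence[float],
    truth: Sequence[bool],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[RocPoint]:
    """ROC points over a threshold grid; labels use the inclusive >= rule."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if p.size != y.size or p.size == 0:
        raise ValueError("probabilities and truth must be equal-length and non-empty")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one example of each class")
    points = []
    for thr in thresholds:
        pred = p >= thr
        tpr = float((pred & y).sum()) / n_pos
        fpr = float((pred & ~y).sum()) / n_neg
        points.append(RocPoint(float(thr), tpr, fpr))
    # monotone thresholding: both rates can only shrink as the bar rises
    for a, b in zip(points, points[1:]):
        assert b.tpr <= a.tpr + 1e-12 and b.fpr <= a.fpr + 1e-12
    return points


def roc_to_frame(points: Sequence[RocPoint]) -> pd.DataFrame:
    return pd.DataFrame([{"threshold": r.threshold, "tpr": r.tpr, "fpr": r.fpr}
                         for r in points])


def score_predictions(manifest: pd.DataFrame, predictions: pd.DataFrame) -> ConfusionCounts:
    """Confusion counts by exact path match of predictions against the manifest.

    Every manifest file must have exactly one prediction; missing or unknown
    paths raise rather than being silently dropped.
    """
    man = manifest.set_index("path")["label"]
    pred = predictions.set_index("path")["label"]
    missing = sorted(set(man.index) - set(pred.index))
    if missing:
        raise ValueError(f"no prediction for manifest files: {missing}")
    unknown = sorted(set(pred.index) - set(man.index))
    if unknown:
        raise ValueError(f"predictions for files not in manifest: {unknown}")
    truth = (man == "buzz")
    guess = (pred.loc[man.index] == "buzz")
    tp = int((truth & guess).sum())
    fp = int((~truth & guess).sum())
    tn = int((~truth & ~guess).sum())
    fn = int((truth & ~guess).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def accuracy_confidence_interval(correct: int, total: int,
                                 level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial CI for overall accuracy."""
    if not (0 <= correct <= total) or total == 0:
        raise ValueError("need 0 <= correct <= total with total > 0")
    alpha = 1.0 - level
    lo = 0.0 if correct == 0 else float(beta.ppf(alpha / 2, correct, total - correct + 1))
    hi = 1.0 if correct == total else float(beta.ppf(1 - alpha / 2, correct + 1,
                                                     total - correct))
    return lo, hi


def metrics_report(c: ConfusionCounts, ci_level: float = 0.95) -> dict:
    """JSON-ready summary of a confusion matrix."""
    sens, spec, bal = confusion_metrics(c)
    correct = c.tp + c.tn
    lo, hi = accuracy_confidence_interval(correct, c.total, ci_level)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": bal,
        "accuracy": correct / c.total,
        "accuracy_ci_low": lo,
        "accuracy_ci_high": hi,
        "counts": {"TP": c.tp, "FP": c.fp, "TN": c.tn, "FN": c.fn},
    }
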