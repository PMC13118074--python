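"""Segmentation quality metrics from pixel-wise confusion counts.

Defect is the positive class throughout.  From the counts TP, FP, FN, TN:

    accuracy    = (TP + TN) / total
    error rate  = (FP + FN) / total * 100   [percent]
    IoU         = TP / (TP + FP + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

Ratios with zero denominators are undefined and reported as NaN, never
silently zeroed.  Useful identities (tested to machine precision):
F1 = 2*TP / (2*TP + FP + FN), IoU = F1 / (2 - F1) and
accuracy + error_rate/100 = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_from_maps",
    "metrics_from_confusion",
    "f1_from_pr",
    "iou_from_pr",
    "error_rate_from_accuracy",
    "report_metric_grid",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies with defect as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion counts must cover at least one pixel")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """The seven reported metrics; ``error_rate`` is in percent."""

    accuracy: float
    error_rate: float
    precision: float
    recall: float
    specificity: float
    f1: float
    iou: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_from_maps(pred, truth, region: str = "fruit_only") -> ConfusionCounts:
    """Tally a decision map against a truth map over the chosen region.

    Maps use {0 background/excluded, 1 healthy, 2 defect}.  With
    ``region='fruit_only'`` only pixels that are non-background in both
    maps are counted; ``'full_frame'`` counts every pixel, treating
    background as healthy (negative).
    """
    pred = np.asarray(getattr(pred, "values", pred))
    truth = np.asarray(getattr(truth, "values", truth))
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    if region == "fruit_only":
        sel = (pred != 0) & (truth != 0)
    elif region == "full_frame":
        sel = np.ones(pred.shape, dtype=bool)
    else:
        raise ValueError("region must be 'fruit_only' or 'full_frame'")
    p = pred[sel] == 2
    t = truth[sel] == 2
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics_from_confusion(c: ConfusionCounts) -> MetricSet:
    """All seven metrics; undefined ratios come back as NaN."""
    total = c.total
    accuracy = (c.tp + c.tn) / total
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    return MetricSet(
        accuracy=accuracy,
        error_rate=(c.fp + c.fn) / total * 100.0,
        precision=precision,
        recall=recall,
        specificity=_ratio(c.tn, c.tn + c.fp),
        f1=f1_from_pr(precision, recall),
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
    )


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if math.isnan(precision) or math.isnan(recall):
        return math.nan
    if precision + recall == 0:
        return math.nan
    return 2.0 * precision * recall / (precision + recall)


def iou_from_pr(precision: float, recall: float) -> float:
    """IoU from precision and recall: P*R / (P + R - P*R)."""
    if math.isnan(precision) or math.isnan(recall):
        return math.nan
    den = precision + recall - precision * recall
    if den == 0:
        return math.nan
    return precision * recall / den


def error_rate_from_accuracy(accuracy: float) -> float:
    """Error rate in percent: (1 - accuracy) * 100."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    return (1.0 - accuracy) * 100.0


METRIC_ORDER = ("accuracy", "error_rate", "f1", "iou",
                "precision", "recall", "specificity")


def report_metric_grid(results: dict[tuple[str, str], MetricSet],
                       decimals: int = 4) -> pd.DataFrame:
    """Metrics-by-(method, mode) table with the best cell flagged per row.

    ``results`` maps (method, mode) pairs to metric sets.  Rows are the
    seven metrics; a ``best`` column names the best column per row (max
    everywhere except error rate, where lower is better).  Values are
    rounded to ``decimals`` for presentation; NaN stays missing.
    """
    if not results:
        raise ValueError("no results to report")
    columns = [f"{method}_{mode}" if mode else method
               for method, mode in results]
    data = {}
    for col, ms in zip(columns, results.values()):
        data[col] = [round(getattr(ms, m), decimals) for m in METRIC_ORDER]
    df = pd.DataFrame(data, index=list(METRIC_ORDER))
    best = []
    for metric in METRIC_ORDER:
        row = df.loc[metric]
        if row.isna().all():
            best.append("")
        elif metric == "error_rate":
            best.append(row.idxmin())
        else:
            best.append(row.idxmax())
    df["best"] = best
    return df
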