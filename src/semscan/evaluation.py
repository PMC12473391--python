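"""Confusion-count metrics, precision-recall curves, and report tables.

SEM is the positive class.  Metrics follow the standard definitions
(precision TP/(TP+FP), recall TP/(TP+FN), accuracy, F1 = 2PR/(P+R)) and
are reported as percentages rounded to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve

__all__ = [
    "EvalReport",
    "confusion_and_metrics",
    "report_from_counts",
    "pr_curve",
    "aggregate_reports",
]


@dataclass
class EvalReport:
    """Confusion counts plus derived percentage metrics (two decimals)."""

    TP: int
    TN: int
    FP: int
    FN: int
    precision: float
    recall: float
    accuracy: float
    f1: float

    @property
    def n_pos(self) -> int:
        return self.TP + self.FN

    @property
    def n_neg(self) -> int:
        return self.TN + self.FP

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_pos"], d["n_neg"] = self.n_pos, self.n_neg
        return d


def _derive(tp: int, tn: int, fp: int, fn: int) -> EvalReport:
    n = tp + tn + fp + fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / n
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(
        TP=tp,
        TN=tn,
        FP=fp,
        FN=fn,
        precision=round(100 * precision, 2),
        recall=round(100 * recall, 2),
        accuracy=round(100 * accuracy, 2),
        f1=round(100 * f1, 2),
    )


def confusion_and_metrics(y_true, y_pred) -> EvalReport:
    """Confusion counts and percentage metrics for binary predictions."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if not (set(np.unique(y_true)) <= {0, 1} and set(np.unique(y_pred)) <= {0, 1}):
        raise ValueError("labels must be binary 0/1 (1 = SEM)")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return _derive(tp, tn, fp, fn)


def report_from_counts(n_pos: int, n_neg: int, fp: int, fn: int) -> EvalReport:
    """Reconstruct the metrics from test-set sample counts and error
    counts (the form results tables are usually published in)."""
    if fn > n_pos or fp > n_neg:
        raise ValueError("error counts exceed sample counts")
    return _derive(tp=n_pos - fn, tn=n_neg - fp, fp=fp, fn=fn)


def pr_curve(y_true, scores):
    """Precision-recall curve over all thresholds plus the average-
    precision (step-rule) area.  ``scores`` are SEM-class probabilities."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("PR curve needs both classes present in y_true")
    precision, recall, thresholds = precision_recall_curve(y_true, scores)
    area = float(average_precision_score(y_true, scores))
    return precision, recall, thresholds, area


def aggregate_reports(reports, ddof: int = 0) -> pd.DataFrame:
    """Mean +/- SD table over per-subject reports.

    ``ddof=0`` (population SD, the convention of the published per-subject
    results table) by default; pass ``ddof=1`` for sample SD.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to aggregate")
    df = pd.DataFrame([r.to_dict() for r in reports])
    cols = ["FP", "FN", "precision", "recall", "accuracy", "f1"]
    out = pd.DataFrame(
        {
            "mean": df[cols].mean().round(2),
            "sd": df[cols].std(ddof=ddof).round(2),
        }
    )
    return out
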