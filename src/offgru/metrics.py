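"""Evaluation metrics for imbalanced binary off-target classification.

Threshold metrics (precision, recall, F1, Matthews correlation
coefficient) are computed from explicit confusion counts:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    MCC       = (TP*TN - FP*FN) /
                sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Degenerate denominators (e.g. no predicted positives) return 0 and raise
the ``degenerate`` flag rather than NaN.  Curve metrics are AUROC and the
non-interpolated area under the precision-recall curve (the latter is the
honest choice at high imbalance, where linear PR interpolation is
systematically optimistic).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import (average_precision_score,
                             precision_recall_curve, roc_auc_score, roc_curve)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    mcc: float
    auroc: float
    prauc: float
    threshold: float = 0.5
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _validated(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if scores.size == 0:
        raise ValueError("cannot evaluate an empty input")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return scores, labels.astype(int)


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts with prediction = (score >= threshold)."""
    scores, labels = _validated(scores, labels)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def scalar_metrics(c: ConfusionCounts) -> dict:
    """Precision, recall, F1 and MCC from confusion counts (total function)."""
    degenerate = False

    def ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    f1 = ratio(2 * precision * recall, precision + recall)
    mcc_den = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                        * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = ratio(c.tp * c.tn - c.fp * c.fn, mcc_den)
    return {"precision": precision, "recall": recall, "f1": f1, "mcc": mcc,
            "degenerate": degenerate}


def curve_metrics(scores, labels) -> dict:
    """AUROC and non-interpolated PRAUC, plus the curve points.

    Raises on one-class input, where the ROC is undefined.
    """
    scores, labels = _validated(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("curve metrics need both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "prauc": float(average_precision_score(labels, scores)),
        "roc_curve": np.column_stack([fpr, tpr]),
        "pr_curve": np.column_stack([rec, prec]),
    }


def evaluate(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Full metric bundle for one score vector."""
    c = confusion(scores, labels, threshold)
    scalars = scalar_metrics(c)
    curves = curve_metrics(scores, labels)
    return MetricReport(
        precision=scalars["precision"], recall=scalars["recall"],
        f1=scalars["f1"], mcc=scalars["mcc"],
        auroc=curves["auroc"], prauc=curves["prauc"],
        threshold=threshold, degenerate=scalars["degenerate"],
    )


def mean_report(reports: list[MetricReport]) -> MetricReport:
    """Fold-averaged report (mean of each metric over folds)."""
    if not reports:
        raise ValueError("no reports to average")
    keys = ("precision", "recall", "f1", "mcc", "auroc", "prauc")
    means = {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}
    return MetricReport(**means, threshold=reports[0].threshold,
                        degenerate=any(r.degenerate for r in reports))
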