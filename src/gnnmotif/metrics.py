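"""Binary-classification metrics and the eight-spoke radar area (AEMR).

Eight metrics — precision, recall, F1, accuracy, specificity, MCC, ROC AUC
and PR AUC — are arranged as the spokes of an equiangular radar chart and
its polygon area summarizes them in one number:

    AEMR = sum_i 1/2 * R_i * R_{i+1} * sin(pi/4),   R_9 = R_1

so a perfect classifier scores 8 * 1/2 * sin(pi/4) = 2*sqrt(2).  MCC can be
negative; the area formula is evaluated literally in that case and the
report carries a flag, since a radar chart cannot display a negative
radius.

Metrics with a zero denominator are reported as 0 together with a flag
(rather than NaN) so the radar area stays computable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

METRIC_ORDER = (
    "precision", "recall", "f1", "acc", "specificity", "mcc", "auc", "prc",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y, y_hat, threshold: float = 0.5) -> ConfusionCounts:
    """Binarize scores at the threshold (ties count positive) and tally."""
    y = np.asarray(y, dtype=int)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0:
        raise ValueError("cannot tally an empty prediction set")
    if y.shape != y_hat.shape:
        raise ValueError("labels and scores must have equal length")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    pred = y_hat >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def _ratio(num: float, den: float, flags: set[str], name: str) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> tuple[dict[str, float], set[str]]:
    """The six threshold metrics from a confusion tally.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean,
    accuracy, specificity = TN/(FP+TN), and the Matthews correlation
    coefficient.  Undefined ratios come back as 0 with the metric's name in
    the flag set.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    flags: set[str] = set()
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    precision = _ratio(tp, tp + fp, flags, "precision")
    recall = _ratio(tp, tp + fn, flags, "recall")
    if precision > 0 and recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        flags.add("f1")
        f1 = 0.0
    specificity = _ratio(tn, fp + tn, flags, "specificity")
    acc = (tp + tn) / c.total
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, mcc_den, flags, "mcc")
    return (
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "acc": acc,
            "specificity": specificity,
            "mcc": mcc,
        },
        flags,
    )


def auc_roc(y, scores) -> float:
    """Area under the ROC curve; equals the Mann-Whitney probability
    P(score+ > score-) + 1/2 P(tie).  Requires both classes."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auc_pr(y, scores) -> float:
    """Area under the precision-recall curve with step-wise (rectangular)
    interpolation.  Requires at least one positive."""
    y = np.asarray(y, dtype=int)
    if int(y.sum()) == 0:
        raise ValueError("PR AUC needs at least one positive")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def aemr(values: dict[str, float] | list[float]) -> float:
    """Radar-polygon area over the eight metrics (closing back to the
    first); evaluated literally even if MCC is negative."""
    if isinstance(values, dict):
        R = [float(values[k]) for k in METRIC_ORDER]
    else:
        R = [float(v) for v in values]
    if len(R) != 8:
        raise ValueError("AEMR needs exactly eight metric values")
    R = R + [R[0]]
    return sum(0.5 * R[i] * R[i + 1] * math.sin(math.pi / 4) for i in range(8))


@dataclass
class MetricsReport:
    """All nine values plus bookkeeping flags."""

    values: dict[str, float]
    aemr: float
    flags: set[str] = field(default_factory=set)

    def radar_vertices(self) -> list[tuple[float, float]]:
        """(x, y) vertices of the radar polygon, spokes at pi/4 steps."""
        return [
            (r * math.cos(i * math.pi / 4), r * math.sin(i * math.pi / 4))
            for i, r in enumerate(self.values[k] for k in METRIC_ORDER)
        ]


def evaluate_predictions(y, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report: six threshold metrics, both curve areas, and AEMR."""
    c = confusion(y, scores, threshold)
    vals, flags = classification_metrics(c)
    vals["auc"] = auc_roc(y, scores)
    vals["prc"] = auc_pr(y, scores)
    if vals["mcc"] < 0:
        flags.add("negative_mcc")
    return MetricsReport(values=vals, aemr=aemr(vals), flags=flags)
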