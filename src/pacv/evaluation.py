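"""Confusion-matrix metrics, participant-aware summaries, train–test gap.

Two complementary summaries exist for participant-aware schemes: the
participant-averaged value (each individual weighted equally, regardless of
trial count) and the pooled/overall value (all test predictions
concatenated, so participants are weighted by trial count). Under LOPO a
held-out participant is single-class, so precision/recall/F1/MCC degenerate
per participant; the zero-denominator convention maps them to 0 and the
headline values for those metrics are the pooled ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be non-empty and of equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def confusion_metrics(y_true, y_pred) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and MCC with class 1 as positive.

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

    Zero denominators map to 0 (precision/recall/F1, and MCC when any
    marginal is empty) — the conservative convention, load-bearing here
    because LOPO test participants are single-class.
    """
    c = confusion_counts(y_true, y_pred)
    acc = (c.tp + c.tn) / c.total
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom > 0 else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1, "mcc": mcc}


@dataclass
class MetricSummary:
    metric: str
    pooled: float
    participant_mean: float | None = None
    participant_sd: float | None = None


@dataclass
class GapSummary:
    """Per-fold train-minus-test accuracy gaps and their mean/SD."""

    gaps: np.ndarray
    mean_gap: float
    sd_gap: float


def _concat(fold_results):
    y_true = np.concatenate([np.asarray(f.y_true) for f in fold_results])
    y_pred = np.concatenate([np.asarray(f.y_pred) for f in fold_results])
    pids = np.concatenate(
        [np.asarray(f.test_participant_per_trial, dtype=object) for f in fold_results]
    )
    return y_true, y_pred, pids


def participant_mean(fold_results, metric: str = "accuracy") -> tuple[float, float]:
    """Unweighted mean and sample SD of a metric across participants.

    The metric is computed per participant over that participant's test
    predictions, then averaged with equal weight per individual.
    """
    y_true, y_pred, pids = _concat(fold_results)
    vals = []
    for p in np.unique(pids.astype(str)):
        m = pids.astype(str) == p
        if not m.any():
            raise ValueError(f"participant {p} has no test predictions")
        vals.append(confusion_metrics(y_true[m], y_pred[m])[metric])
    vals = np.asarray(vals)
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd


def pooled_overall(fold_results, metric: str = "accuracy") -> float:
    """Metric on the concatenation of all test predictions across folds."""
    y_true, y_pred, _ = _concat(fold_results)
    return confusion_metrics(y_true, y_pred)[metric]


def train_test_gap(fold_results) -> GapSummary:
    """Per-fold (train accuracy − test accuracy) and its mean/SD across folds.

    Only meaningful for participant-aware strategies (LOPO, nested), where
    train and test participants are disjoint; refused otherwise because a
    shared participant on both sides makes the gap uninterpretable.
    """
    for f in fold_results:
        if getattr(f, "strategy", None) not in ("lopo", "nested"):
            raise ValueError(
                "train-test gap is only computed for participant-aware "
                "strategies (lopo, nested); got "
                f"'{getattr(f, 'strategy', None)}'"
            )
        if f.train_accuracy is None:
            raise ValueError("fold results lack train_accuracy")
    gaps = np.array(
        [f.train_accuracy - confusion_metrics(f.y_true, f.y_pred)["accuracy"] for f in fold_results]
    )
    sd = float(np.std(gaps, ddof=1)) if len(gaps) > 1 else 0.0
    return GapSummary(gaps=gaps, mean_gap=float(np.mean(gaps)), sd_gap=sd)


def summarize(fold_results, participant_aware: bool) -> list[MetricSummary]:
    """Pooled (and, where meaningful, participant-averaged) metric summaries."""
    out = []
    for m in METRIC_NAMES:
        pooled = pooled_overall(fold_results, m)
        if participant_aware:
            mean, sd = participant_mean(fold_results, m)
            out.append(MetricSummary(metric=m, pooled=pooled, participant_mean=mean,
                                     participant_sd=sd))
        else:
            out.append(MetricSummary(metric=m, pooled=pooled))
    return out
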