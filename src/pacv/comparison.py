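"""Cross-strategy bias, participant-level rank stability, efficiency profiles.

Bias Δ is a strategy's metric minus the participant-aware baseline's
(positive = overestimation); MAB averages |Δ| over the five confusion-matrix
metrics into one scalar per (model, strategy). Rank stability ranks the
models within each participant by accuracy (rank 1 = best, ties averaged)
and summarizes mean/SD/best/worst rank per model. The efficiency profile
collects wall-clock training time per fold, per-sample inference latency,
and serialized model size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .evaluation import METRIC_NAMES, confusion_metrics


def bias_delta(strategy_value: float, baseline_value: float) -> float:
    """Δ = strategy metric − participant-aware baseline metric."""
    if not (np.isfinite(strategy_value) and np.isfinite(baseline_value)):
        raise ValueError("bias requires finite metric values")
    return float(strategy_value) - float(baseline_value)


def mean_absolute_bias(deltas) -> float:
    """MAB: mean of |Δ| over the five metrics (one Δ per metric)."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.shape != (len(METRIC_NAMES),):
        raise ValueError(f"expected one delta per metric ({len(METRIC_NAMES)}); got {deltas.shape}")
    return float(np.mean(np.abs(deltas)))


@dataclass
class RankTable:
    """Participants × models tie-averaged accuracy ranks plus summaries."""

    participants: list[str]
    models: list[str]
    ranks: np.ndarray  # shape (n_participants, n_models)
    summary: pd.DataFrame  # per model: mean_rank, sd_rank, best_rank, worst_rank


def within_participant_ranks(accuracy: np.ndarray, participants, models) -> RankTable:
    """Rank models within each participant by accuracy, highest = rank 1.

    Ties receive the average of the spanned ranks, so each row still sums to
    n_models (n_models + 1) / 2. Summaries (mean, sample SD, best = min,
    worst = max) are taken across participants.
    """
    A = np.asarray(accuracy, dtype=float)
    if A.size == 0:
        raise ValueError("accuracy matrix is empty")
    if not np.all(np.isfinite(A)):
        raise ValueError("accuracy matrix contains non-finite entries")
    ranks = np.vstack([rankdata(-row, method="average") for row in A])
    sd = np.std(ranks, axis=0, ddof=1) if ranks.shape[0] > 1 else np.zeros(ranks.shape[1])
    summary = pd.DataFrame(
        {
            "model": list(models),
            "mean_rank": ranks.mean(axis=0),
            "sd_rank": sd,
            "best_rank": ranks.min(axis=0),
            "worst_rank": ranks.max(axis=0),
        }
    )
    return RankTable(
        participants=list(participants), models=list(models), ranks=ranks, summary=summary
    )


def participant_accuracy_matrix(results_by_model: dict[str, list]) -> tuple[np.ndarray, list, list]:
    """Per-participant accuracy matrix from LOPO/nested fold results.

    ``results_by_model`` maps model name -> list of FoldResult from one
    participant-aware run. Returns (matrix, participants, models) with rows
    ordered by ascending participant ID.
    """
    models = list(results_by_model)
    per_model: dict[str, dict[str, float]] = {}
    for m, folds in results_by_model.items():
        acc: dict[str, float] = {}
        for f in folds:
            pids = np.asarray(f.test_participant_per_trial).astype(str)
            for p in np.unique(pids):
                mask = pids == p
                acc[p] = confusion_metrics(np.asarray(f.y_true)[mask],
                                           np.asarray(f.y_pred)[mask])["accuracy"]
        per_model[m] = acc
    participants = sorted(per_model[models[0]])
    A = np.array([[per_model[m][p] for m in models] for p in participants])
    return A, participants, models


@dataclass
class EfficiencyProfile:
    train_time_s_per_fold: float
    inference_ms_per_sample: float
    model_size_mb: float


def efficiency_profile(fold_results) -> EfficiencyProfile:
    """Mean per-fold training time, per-sample inference latency, model size.

    Nested fold results already include the inner-search runtime in their
    train time. Inference latency is total prediction wall-clock over total
    test samples; size is the serialized model size averaged over folds.
    """
    n_samples = sum(len(f.y_pred) for f in fold_results)
    total_infer_ms = sum(f.inference_time_ms * len(f.y_pred) for f in fold_results)
    return EfficiencyProfile(
        train_time_s_per_fold=float(np.mean([f.train_time_s for f in fold_results])),
        inference_ms_per_sample=total_infer_ms / n_samples if n_samples else 0.0,
        model_size_mb=float(np.mean([f.model_size_bytes for f in fold_results])) / 2**20,
    )


def bias_report(
    metrics_by_strategy: dict[str, dict[str, float]], baseline: str = "lopo"
) -> pd.DataFrame:
    """Δ per (strategy, metric) against a participant-aware baseline, plus MAB.

    ``metrics_by_strategy`` maps strategy -> {metric: value} for one model.
    """
    if baseline not in metrics_by_strategy:
        raise ValueError(f"baseline '{baseline}' missing from supplied strategies")
    base = metrics_by_strategy[baseline]
    rows = []
    for strat, vals in metrics_by_strategy.items():
        deltas = [bias_delta(vals[m], base[m]) for m in METRIC_NAMES]
        mab = mean_absolute_bias(deltas)
        for m, d in zip(METRIC_NAMES, deltas):
            rows.append({"strategy": strat, "metric": m, "delta": d, "mab": mab,
                         "baseline": baseline})
    return pd.DataFrame(rows)
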