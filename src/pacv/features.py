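"""Signal summarization, univariate FDR filtering, importance ranking, scaling.

A trial's multi-channel waveforms are condensed into 13 summary statistics
per signal (48 signals -> 624 features). The feature set is then screened by
a per-feature rank-sum test with Benjamini–Hochberg control, ranked once by
gradient-boosting importance on pooled data, and truncated to a fixed top-k
before any cross-validation experiment. Standardization is leakage-safe:
scaler parameters are estimated on a training split only and applied
unchanged to the matching test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .data import TrialTable
from .synthetic import RawTrialSignals

__all__ = [
    "STAT_DESCRIPTORS",
    "SignalFeaturizer",
    "SelectionResult",
    "ScalerParams",
    "summarize_signals",
    "fdr_filter",
    "rank_importance",
    "select_top_k",
    "fit_scaler",
    "apply_scaler",
    "features_from_signals",
]


def _autocorr(x: np.ndarray, lag: int) -> float:
    # sum_t (x_t - xbar)(x_{t+lag} - xbar) / sum_t (x_t - xbar)^2 ; 0 on flat input
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        return 0.0
    return float(np.dot(xc[:-lag], xc[lag:]) / denom)


def _skewness(x: np.ndarray) -> float:
    if np.ptp(x) == 0.0 or x.size < 3:
        return 0.0
    v = stats.skew(x, bias=False)
    return float(v) if np.isfinite(v) else 0.0


def _kurtosis(x: np.ndarray) -> float:
    if np.ptp(x) == 0.0 or x.size < 4:
        return 0.0
    v = stats.kurtosis(x, fisher=True, bias=False)
    return float(v) if np.isfinite(v) else 0.0


# The 13 descriptors. sd/variance are population moments (divide by n);
# skewness is the adjusted Fisher–Pearson coefficient; kurtosis is Fisher
# excess; percentiles interpolate linearly; counts use strict inequality.
# Zero-variance signals map skewness/kurtosis/autocorrelations to 0.
STAT_DESCRIPTORS: dict[str, callable] = {
    "mean": lambda x: float(np.mean(x)),
    "sd": lambda x: float(np.std(x)),
    "variance": lambda x: float(np.var(x)),
    "skewness": _skewness,
    "kurtosis": _kurtosis,
    "p10": lambda x: float(np.percentile(x, 10)),
    "p50": lambda x: float(np.percentile(x, 50)),
    "p90": lambda x: float(np.percentile(x, 90)),
    "autocorr_lag1": lambda x: _autocorr(x, 1),
    "autocorr_lag2": lambda x: _autocorr(x, 2),
    "count_above_mean": lambda x: float(np.sum(x > np.mean(x))),
    "count_below_mean": lambda x: float(np.sum(x < np.mean(x))),
    "abs_sum_of_changes": lambda x: float(np.sum(np.abs(np.diff(x)))),
}


def summarize_signals(trial: RawTrialSignals) -> tuple[np.ndarray, list[str]]:
    """Condense one trial's signals into the 13-statistic feature vector.

    Returns ``(values, names)`` with names ``<signal>__<descriptor>`` and
    length ``n_signals * 13``.
    """
    sigs = np.asarray(trial.signals, dtype=float)
    if sigs.shape[0] < 1:
        raise ValueError("trial must contain at least one signal")
    if sigs.shape[1] < 3:
        raise ValueError(
            f"signal length {sigs.shape[1]} < 3: lag-2 autocorrelation undefined"
        )
    values, names = [], []
    for name, row in zip(trial.signal_names, sigs):
        for stat, fn in STAT_DESCRIPTORS.items():
            values.append(fn(row))
            names.append(f"{name}__{stat}")
    return np.asarray(values), names


class SignalFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping raw trials to the summary-feature table."""

    def fit(self, X, y=None):
        self.n_features_out_ = len(X[0].signal_names) * len(STAT_DESCRIPTORS) if len(X) else 0
        return self

    def transform(self, X: list[RawTrialSignals]) -> np.ndarray:
        rows = [summarize_signals(t)[0] for t in X]
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        raise NotImplementedError("names depend on the trial; use summarize_signals")


def features_from_signals(trials: list[RawTrialSignals]) -> TrialTable:
    """Build a TrialTable by summarizing every trial in a signal set."""
    first_vals, names = summarize_signals(trials[0])
    feats = np.vstack([first_vals] + [summarize_signals(t)[0] for t in trials[1:]])
    return TrialTable(
        features=feats,
        labels=np.array([t.label for t in trials], dtype=int),
        participant_ids=np.array([t.participant_id for t in trials], dtype=object),
        trial_indices=np.array([t.trial_index for t in trials], dtype=int),
        feature_names=names,
    )


@dataclass
class SelectionResult:
    """Outcome of the screening / ranking / top-k pipeline."""

    feature_names: list[str]
    p_values: np.ndarray | None = None
    retained: np.ndarray | None = None  # boolean mask over feature_names
    importance: dict[str, float] = field(default_factory=dict)
    ranking: list[str] = field(default_factory=list)
    top_k: list[str] = field(default_factory=list)

    @property
    def retained_names(self) -> list[str]:
        if self.retained is None:
            return list(self.feature_names)
        return [n for n, keep in zip(self.feature_names, self.retained) if keep]


def fdr_filter(table: TrialTable, alpha: float = 0.05) -> SelectionResult:
    """Per-feature two-sided rank-sum screen with Benjamini–Hochberg control.

    Each feature is tested against the binary label with a two-sided
    Mann–Whitney U test; BH at level ``alpha`` decides retention.
    Zero-variance features get p = 1.
    """
    y = np.asarray(table.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("fdr_filter requires both classes present")
    p = np.ones(table.n_features)
    for j in range(table.n_features):
        col = table.features[:, j]
        if np.ptp(col) == 0.0:
            p[j] = 1.0
            continue
        a, b = col[y == 1], col[y == 0]
        p[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    retained = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    return SelectionResult(feature_names=list(table.feature_names), p_values=p, retained=retained)


def rank_importance(
    table: TrialTable, retained: np.ndarray | None = None, seed: int = 42
) -> SelectionResult:
    """Rank retained features by gradient-boosting impurity importance.

    One ensemble is fit on the pooled table (fixed seed) — the study's
    deliberate pre-experimental, fold-independent ranking — and features are
    ordered by descending importance, ties broken by name.
    """
    from .models import ModelAdapter, build_adapter

    if retained is None:
        retained = np.ones(table.n_features, dtype=bool)
    retained = np.asarray(retained, dtype=bool)
    names = [n for n, keep in zip(table.feature_names, retained) if keep]
    if not names:
        raise ValueError("no retained features to rank")
    if len(np.unique(table.labels)) < 2:
        raise ValueError("rank_importance requires both classes present")
    adapter: ModelAdapter = build_adapter("gradient_boosting", seed=seed)
    X = table.features[:, retained]
    adapter.fit(X, np.asarray(table.labels, dtype=int))
    imp = np.asarray(adapter.estimator_.feature_importances_, dtype=float)
    imp = np.where(np.isfinite(imp) & (imp > 0), imp, 0.0)
    order = sorted(range(len(names)), key=lambda i: (-imp[i], names[i]))
    return SelectionResult(
        feature_names=list(table.feature_names),
        retained=retained,
        importance={names[i]: float(imp[i]) for i in order},
        ranking=[names[i] for i in order],
    )


def select_top_k(ranking: list[str], k: int = 10) -> list[str]:
    """First ``min(k, len(ranking))`` names, order preserved.

    The truncation is fixed a priori and frozen before any cross-validation
    experiment; it is never revisited per fold.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return list(ranking[:k])


@dataclass
class ScalerParams:
    """Per-feature train-split mean and population standard deviation."""

    mean: np.ndarray
    sd: np.ndarray


def fit_scaler(train_features: np.ndarray) -> ScalerParams:
    """Estimate z-scaling parameters on a training split only."""
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training split must be a non-empty 2-D matrix")
    return ScalerParams(mean=X.mean(axis=0), sd=X.std(axis=0))


def apply_scaler(params: ScalerParams, features: np.ndarray) -> np.ndarray:
    """Apply train-split z-scaling; zero-sd columns map to 0."""
    X = np.asarray(features, dtype=float)
    sd = np.where(params.sd > 0, params.sd, 1.0)
    out = (X - params.mean) / sd
    out[:, params.sd == 0] = 0.0
    return out


class TrainOnlyScaler(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around fit_scaler/apply_scaler."""

    def fit(self, X, y=None):
        self.params_ = fit_scaler(X)
        return self

    def transform(self, X):
        return apply_scaler(self.params_, X)
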