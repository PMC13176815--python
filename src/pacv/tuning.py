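"""Strategy execution: fixed-configuration runs and nested inner-loop tuning.

The three single-level schemes (trial-wise stratified 10-fold, group 3-fold,
LOPO) evaluate each family at its fixed configuration. The nested scheme
runs, per held-out participant, a grid search over the capacity-ordered
configurations scored by macro-F1 averaged over the group-3 inner folds;
configurations within 0.5 percentage points of the best are treated as
indistinguishable and the simplest wins (lower variance at equal skill).
The winner is refit on the full outer-train set and evaluated once on the
held-out participant — tuning never touches outer-test data. Feature
scaling is refit inside every training split, including the inner ones.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .data import TrialTable
from .evaluation import confusion_metrics
from .features import apply_scaler, fit_scaler
from .models import HyperParamGrid, ModelAdapter, build_adapter, default_grid, serialized_size
from .splitters import FoldAssignment, group_kfold, lopo, nested_plan, stratified_kfold

logger = logging.getLogger(__name__)

STRATEGY_NAMES = ("stratified_kfold", "group_kfold", "lopo", "nested")

TIE_BREAK_WINDOW = 0.005  # 0.5 percentage points of mean inner macro-F1


@dataclass(frozen=True)
class StrategySpec:
    """One of the four validation designs.

    ``k`` is fixed by convention: 10 for the trial-wise stratified scheme,
    3 for group K-fold and for the nested inner loop. Only the nested design
    tunes; the single-level baselines use fixed configurations.
    """

    name: str
    k: int | None = None
    seed: int = 42
    tuned: bool | None = None

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy '{self.name}'")
        if self.k is None:
            object.__setattr__(self, "k", {"stratified_kfold": 10}.get(self.name, 3))
        if self.tuned is None:
            object.__setattr__(self, "tuned", self.name == "nested")
        if (self.name == "nested") != self.tuned:
            raise ValueError("tuned=True iff strategy is 'nested'")


@dataclass
class FoldResult:
    """Predictions and bookkeeping for one executed fold."""

    fold_id: int
    strategy: str
    test_participants: frozenset
    train_participants: frozenset
    y_true: np.ndarray
    y_pred: np.ndarray
    test_participant_per_trial: np.ndarray
    test_trials: np.ndarray
    train_accuracy: float | None = None
    chosen_config: dict | None = None
    train_time_s: float = 0.0
    inference_time_ms: float = 0.0
    model_size_bytes: int = 0
    inner_participant_audit: list[tuple[frozenset, frozenset]] = field(default_factory=list)


@dataclass
class InnerSelection:
    """Result of one inner-loop grid search."""

    mean_scores: list[float]  # aligned with grid.configs
    chosen_index: int
    chosen_config: dict
    tie_break_applied: bool


def macro_f1(y_true, y_pred) -> float:
    """Unweighted mean of class-0 and class-1 F1 (zero denominators -> 0)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be non-empty and of equal length")
    f1_pos = confusion_metrics(y_true, y_pred)["f1"]
    f1_neg = confusion_metrics(1 - y_true, 1 - y_pred)["f1"]
    return 0.5 * (f1_pos + f1_neg)


def _fit_scaled(adapter: ModelAdapter, table: TrialTable, train_rows, config=None):
    """Fit (a clone of) the adapter on a scaled training split."""
    sub = adapter.clone(config=config) if config is not None else adapter.clone()
    scaler = fit_scaler(table.features[train_rows])
    sub.fit(apply_scaler(scaler, table.features[train_rows]),
            np.asarray(table.labels, dtype=int)[train_rows])
    return sub, scaler


def inner_select(
    family_name: str,
    grid: HyperParamGrid,
    inner_folds: list[FoldAssignment],
    table: TrialTable,
    seed: int = 42,
    inner_metric: str = "macro_f1",
) -> InnerSelection:
    """Grid search over the inner folds with the simplicity tie-break.

    Every configuration is trained on each inner-train split (scaling refit
    per split) and scored on its inner-validation split; scores are averaged
    over folds. Among configurations within ``TIE_BREAK_WINDOW`` of the
    maximum, the lowest capacity index wins. Configurations that fail to fit
    on any inner fold are excluded with a warning; if all fail, an error is
    raised.
    """
    if len(inner_folds) < 2:
        raise ValueError("inner selection needs >= 2 inner folds")
    if inner_metric not in ("macro_f1", "accuracy"):
        raise ValueError("inner_metric must be 'macro_f1' or 'accuracy'")
    proto = build_adapter(family_name, seed=seed)
    y = np.asarray(table.labels, dtype=int)
    mean_scores: list[float] = []
    ok = []
    for config in grid.configs:
        scores = []
        try:
            for f in inner_folds:
                model, scaler = _fit_scaled(proto, table, f.train_trials, config=config)
                pred = model.predict(apply_scaler(scaler, table.features[f.test_trials]))
                if inner_metric == "macro_f1":
                    scores.append(macro_f1(y[f.test_trials], pred))
                else:
                    scores.append(confusion_metrics(y[f.test_trials], pred)["accuracy"])
            mean_scores.append(float(np.mean(scores)))
            ok.append(True)
        except Exception as err:  # noqa: BLE001 - a failing config is excluded, not fatal
            logger.warning("excluding %s config %s: %s", family_name, config, err)
            mean_scores.append(float("-inf"))
            ok.append(False)
    if not any(ok):
        raise RuntimeError(f"every configuration failed to fit for family '{family_name}'")
    chosen, tie_break = select_with_tie_break(mean_scores, window=TIE_BREAK_WINDOW)
    return InnerSelection(
        mean_scores=mean_scores,
        chosen_index=chosen,
        chosen_config=dict(grid.configs[chosen]),
        tie_break_applied=tie_break,
    )


def select_with_tie_break(mean_scores, window: float = TIE_BREAK_WINDOW) -> tuple[int, bool]:
    """Pick the simplest configuration within ``window`` of the best score.

    ``mean_scores`` are ordered by capacity (index 0 = simplest); scores of
    ``-inf`` mark excluded configurations. Returns ``(chosen_index,
    tie_break_applied)`` where the flag is set when the winner differs from
    the plain argmax.
    """
    finite = [s for s in mean_scores if np.isfinite(s)]
    if not finite:
        raise ValueError("no finite scores to select from")
    best = max(finite)
    argmax = min(i for i, s in enumerate(mean_scores) if s == best)
    chosen = min(
        i for i, s in enumerate(mean_scores) if np.isfinite(s) and s >= best - window
    )
    return chosen, chosen != argmax


def _evaluate_fold(
    adapter: ModelAdapter,
    table: TrialTable,
    fold: FoldAssignment,
    strategy: str,
    config: dict | None = None,
    extra_train_time: float = 0.0,
    inner_audit=None,
) -> FoldResult:
    y = np.asarray(table.labels, dtype=int)
    t0 = time.perf_counter()
    model, scaler = _fit_scaled(adapter, table, fold.train_trials, config=config)
    train_time = time.perf_counter() - t0 + extra_train_time
    X_test = apply_scaler(scaler, table.features[fold.test_trials])
    t1 = time.perf_counter()
    pred = model.predict(X_test)
    infer_ms = (time.perf_counter() - t1) * 1000.0 / max(len(pred), 1)
    train_pred = model.predict(apply_scaler(scaler, table.features[fold.train_trials]))
    train_acc = confusion_metrics(y[fold.train_trials], train_pred)["accuracy"]
    return FoldResult(
        fold_id=fold.fold_id,
        strategy=strategy,
        test_participants=fold.test_participants,
        train_participants=fold.train_participants,
        y_true=y[fold.test_trials],
        y_pred=pred,
        test_participant_per_trial=table.participant_ids[fold.test_trials].astype(str),
        test_trials=fold.test_trials,
        train_accuracy=train_acc,
        chosen_config=dict(config) if config is not None else None,
        train_time_s=train_time,
        inference_time_ms=infer_ms,
        model_size_bytes=serialized_size(model),
        inner_participant_audit=list(inner_audit or []),
    )


def run_strategy(
    table: TrialTable,
    spec: StrategySpec,
    family_name: str,
    grid: HyperParamGrid | None = None,
    seed: int | None = None,
    inner_metric: str = "macro_f1",
) -> list[FoldResult]:
    """Execute one (strategy, model family) run and return per-fold results.

    Single-level schemes fit the family's fixed configuration per fold;
    the nested scheme tunes per outer fold on its inner group folds, then
    retrains on the full outer-train set and evaluates once on the held-out
    participant. Nested train time includes the full inner search.
    """
    seed = spec.seed if seed is None else seed
    adapter = build_adapter(family_name, seed=seed)
    if spec.name == "stratified_kfold":
        folds = stratified_kfold(table, k=spec.k, seed=spec.seed)
        return [_evaluate_fold(adapter, table, f, spec.name) for f in folds]
    if spec.name == "group_kfold":
        folds = group_kfold(table, k=spec.k)
        return [_evaluate_fold(adapter, table, f, spec.name) for f in folds]
    if spec.name == "lopo":
        folds = lopo(table)
        return [_evaluate_fold(adapter, table, f, spec.name) for f in folds]
    # nested
    if grid is None:
        grid = default_grid(family_name)
    plan = nested_plan(table, inner_k=spec.k)
    results = []
    for ofold, inner_folds in zip(plan.outer, plan.inner):
        t0 = time.perf_counter()
        sel = inner_select(
            family_name, grid, inner_folds, table, seed=seed, inner_metric=inner_metric
        )
        inner_time = time.perf_counter() - t0
        audit = [(f.train_participants, f.test_participants) for f in inner_folds]
        results.append(
            _evaluate_fold(
                adapter,
                table,
                ofold,
                spec.name,
                config=sel.chosen_config,
                extra_train_time=inner_time,
                inner_audit=audit,
            )
        )
    return results
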