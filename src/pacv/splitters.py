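"""The four fold-construction schemes, with deterministic semantics.

* trial-wise stratified K-fold (k=10): preserves label proportions per fold
  but lets one participant's trials straddle train and test — the leakage
  mechanism under study;
* group K-fold (k=3): participants are atomic, folds balance trial counts;
* leave-one-participant-out (LOPO): one fold per participant;
* nested: LOPO outer evaluation with a group-3 inner split of the outer-train
  participants for hyperparameter tuning.

Splitter classes follow the sklearn ``BaseCrossValidator`` API
(``split(X, y, groups)`` / ``get_n_splits``); the module-level functions
return explicit :class:`FoldAssignment` records for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import BaseCrossValidator, StratifiedKFold

from .data import TrialTable


@dataclass
class FoldAssignment:
    """One train/test split of trial row indices and the participants it isolates."""

    fold_id: int
    train_trials: np.ndarray
    test_trials: np.ndarray
    test_participants: frozenset
    train_participants: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.train_trials = np.asarray(self.train_trials, dtype=int)
        self.test_trials = np.asarray(self.test_trials, dtype=int)
        if np.intersect1d(self.train_trials, self.test_trials).size:
            raise ValueError("train and test trial sets overlap")


@dataclass
class NestedPlan:
    """LOPO outer folds, each carrying a group-3 inner split of its train set.

    Invariant: the outer-test participant appears in no inner train or
    validation split, and every inner validation split is a union of whole
    participants.
    """

    outer: list[FoldAssignment]
    inner: list[list[FoldAssignment]]  # inner[i] belongs to outer[i]


def _assignments(table: TrialTable, splits, fold_ids=None) -> list[FoldAssignment]:
    pids = table.participant_ids.astype(str)
    out = []
    for i, (tr, te) in enumerate(splits):
        out.append(
            FoldAssignment(
                fold_id=i if fold_ids is None else fold_ids[i],
                train_trials=np.asarray(tr, dtype=int),
                test_trials=np.asarray(te, dtype=int),
                test_participants=frozenset(pids[te]),
                train_participants=frozenset(pids[tr]),
            )
        )
    return out


class StratifiedTrialKFold(BaseCrossValidator):
    """Trial-wise stratified K-fold (participant identity deliberately ignored).

    Shuffles with the given seed, then allocates trials so per-class test
    counts differ by at most one across folds. Thin wrapper over sklearn's
    ``StratifiedKFold(shuffle=True)``.
    """

    def __init__(self, n_splits: int = 10, seed: int = 42):
        self.n_splits = n_splits
        self.seed = seed

    def get_n_splits(self, X=None, y=None, groups=None):
        return self.n_splits

    def split(self, X, y, groups=None):
        y = np.asarray(y)
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < self.n_splits:
            raise ValueError(
                f"stratification impossible: smallest class has {counts.min()} "
                f"trials < k={self.n_splits}"
            )
        inner = StratifiedKFold(n_splits=self.n_splits, shuffle=True, random_state=self.seed)
        yield from inner.split(np.zeros((len(y), 1)), y)

    def _iter_test_indices(self, X=None, y=None, groups=None):  # pragma: no cover
        for _, te in self.split(X, y, groups):
            yield te


class ParticipantGroupKFold(BaseCrossValidator):
    """Group K-fold with participants as atomic groups.

    Deterministic greedy assignment: participants sorted by trial count
    descending (ties by ID) go to the fold with the smallest running trial
    total (ties by fold id). Balances trial counts; with 5–10 trials per
    participant the per-fold participant counts come out within one of each
    other as well.
    """

    def __init__(self, n_splits: int = 3):
        self.n_splits = n_splits

    def get_n_splits(self, X=None, y=None, groups=None):
        return self.n_splits

    def group_assignment(self, groups) -> dict:
        """participant -> fold id, per the greedy balancing rule."""
        groups = np.asarray(groups).astype(str)
        uniq, counts = np.unique(groups, return_counts=True)
        if len(uniq) < self.n_splits:
            raise ValueError(
                f"{len(uniq)} participants < k={self.n_splits}: cannot form groups"
            )
        order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
        loads = [0] * self.n_splits
        fold_of: dict[str, int] = {}
        for i in order:
            f = min(range(self.n_splits), key=lambda j: (loads[j], j))
            fold_of[uniq[i]] = f
            loads[f] += counts[i]
        return fold_of

    def split(self, X, y=None, groups=None):
        if groups is None:
            raise ValueError("groups (participant IDs) are required")
        groups = np.asarray(groups).astype(str)
        fold_of = self.group_assignment(groups)
        folds = np.array([fold_of[g] for g in groups])
        idx = np.arange(len(groups))
        for f in range(self.n_splits):
            yield idx[folds != f], idx[folds == f]

    def _iter_test_indices(self, X=None, y=None, groups=None):  # pragma: no cover
        for _, te in self.split(X, y, groups):
            yield te


class LeaveOneParticipantOut(BaseCrossValidator):
    """One fold per participant, ordered by ascending participant ID."""

    def get_n_splits(self, X=None, y=None, groups=None):
        return len(np.unique(np.asarray(groups).astype(str)))

    def split(self, X, y=None, groups=None):
        if groups is None:
            raise ValueError("groups (participant IDs) are required")
        groups = np.asarray(groups).astype(str)
        uniq = np.unique(groups)
        if len(uniq) < 2:
            raise ValueError("LOPO requires >= 2 participants (training set would be empty)")
        idx = np.arange(len(groups))
        for p in uniq:
            yield idx[groups != p], idx[groups == p]

    def _iter_test_indices(self, X=None, y=None, groups=None):  # pragma: no cover
        for _, te in self.split(X, y, groups):
            yield te


def stratified_kfold(table: TrialTable, k: int = 10, seed: int = 42) -> list[FoldAssignment]:
    """Trial-wise stratified K-fold assignments over a trial table."""
    cv = StratifiedTrialKFold(n_splits=k, seed=seed)
    return _assignments(table, cv.split(table.features, table.labels))


def group_kfold(table: TrialTable, k: int = 3) -> list[FoldAssignment]:
    """Participant-atomic group K-fold assignments."""
    cv = ParticipantGroupKFold(n_splits=k)
    return _assignments(table, cv.split(table.features, groups=table.participant_ids))


def lopo(table: TrialTable) -> list[FoldAssignment]:
    """Leave-one-participant-out assignments, ascending participant ID."""
    cv = LeaveOneParticipantOut()
    return _assignments(
        table, cv.split(table.features, groups=table.participant_ids)
    )


def nested_plan(table: TrialTable, inner_k: int = 3) -> NestedPlan:
    """LOPO outer folds, each with a group-``inner_k`` split of its train set.

    Inner splits are expressed in the *parent table's* row indices. Fails if
    any outer-train set has fewer than ``inner_k`` participants rather than
    silently shrinking the inner loop.
    """
    n_participants = len(table.participants)
    if n_participants < inner_k + 1:
        raise ValueError(
            f"nested plan needs >= {inner_k + 1} participants "
            f"(inner_k={inner_k} groups plus one held out); got {n_participants}"
        )
    outer = lopo(table)
    gkf = ParticipantGroupKFold(n_splits=inner_k)
    pids = table.participant_ids.astype(str)
    inner_all: list[list[FoldAssignment]] = []
    for ofold in outer:
        rows = ofold.train_trials
        inner_splits = [
            (rows[tr], rows[te]) for tr, te in gkf.split(rows, groups=pids[rows])
        ]
        inner_all.append(_assignments(table, inner_splits))
    return NestedPlan(outer=outer, inner=inner_all)


def folds_to_frame(folds: list[FoldAssignment], table: TrialTable) -> pd.DataFrame:
    """Audit export: one row per (fold, role, trial, participant)."""
    pids = table.participant_ids.astype(str)
    rows = []
    for f in folds:
        for role, trials in (("train", f.train_trials), ("test", f.test_trials)):
            for t in trials:
                rows.append((f.fold_id, role, int(t), pids[t]))
    return pd.DataFrame(rows, columns=["fold_id", "role", "trial_row", "participant_id"])
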