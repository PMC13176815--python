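import numpy as np
import pytest

from pacv import (
    GeneratorConfig,
    TrialTable,
    generate_feature_table,
    group_kfold,
    lopo,
    nested_plan,
    stratified_kfold,
)
from pacv.splitters import ParticipantGroupKFold


def _partition_ok(folds, n_trials):
    tests = [set(f.test_trials.tolist()) for f in folds]
    union = set().union(*tests)
    pairwise_disjoint = sum(len(t) for t in tests) == len(union)
    return pairwise_disjoint and union == set(range(n_trials))


def _balanced_table(n_per_class=10):
    n = 2 * n_per_class
    return TrialTable(
        features=np.random.default_rng(0).normal(size=(n, 2)),
        labels=np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)],
        participant_ids=np.array([f"P{i}" for i in range(n)], dtype=object),
        trial_indices=np.ones(n, int),
    )


class TestStratifiedKFold:
    def test_two_folds_forced_balance(self):
        t = _balanced_table(10)
        folds = stratified_kfold(t, k=2, seed=0)
        for f in folds:
            y = t.labels[f.test_trials]
            assert len(y) == 10 and y.sum() == 5

    def test_fold_sizes_on_623_trials(self, cohort_623):
        folds = stratified_kfold(cohort_623, k=10, seed=42)
        sizes = sorted(len(f.test_trials) for f in folds)
        # 623 = 10*62 + 3
        assert sizes == [62] * 7 + [63] * 3

    def test_class_counts_within_one_of_proportional(self, cohort_table):
        folds = stratified_kfold(cohort_table, k=10, seed=42)
        for cls in (0, 1):
            counts = [int(np.sum(cohort_table.labels[f.test_trials] == cls)) for f in folds]
            assert max(counts) - min(counts) <= 1

    def test_participants_straddle_folds(self, cohort_table):
        """Pigeonhole: a participant with more trials than n/k must straddle."""
        folds = stratified_kfold(cohort_table, k=10, seed=42)
        pids = cohort_table.participant_ids.astype(str)
        straddlers = 0
        for p in cohort_table.participants:
            fold_of_trials = {
                f.fold_id for f in folds for tr in f.test_trials if pids[tr] == p
            }
            if len(fold_of_trials) > 1:
                straddlers += 1
        assert straddlers > 0  # the leakage mechanism exists by design

    def test_partition(self, cohort_table):
        assert _partition_ok(stratified_kfold(cohort_table, k=10, seed=42),
                             cohort_table.n_trials)

    def test_determinism_and_seed_sensitivity(self, cohort_table):
        a = stratified_kfold(cohort_table, k=10, seed=1)
        b = stratified_kfold(cohort_table, k=10, seed=1)
        c = stratified_kfold(cohort_table, k=10, seed=2)
        assert all(np.array_equal(x.test_trials, y.test_trials) for x, y in zip(a, b))
        assert any(not np.array_equal(x.test_trials, y.test_trials) for x, y in zip(a, c))

    def test_small_class_rejected(self):
        t = _balanced_table(3)
        with pytest.raises(ValueError, match="class"):
            stratified_kfold(t, k=10)


class TestGroupKFold:
    def test_three_participants_three_folds_is_lopo(self, tiny_table):
        t = tiny_table
        t.participant_ids = np.array(["A", "A", "B", "B", "C", "C"], dtype=object)
        t.trial_indices = np.array([1, 2, 1, 2, 1, 2])
        folds = group_kfold(t, k=3)
        assert sorted(len(f.test_participants) for f in folds) == [1, 1, 1]

    def test_no_participant_overlap(self, cohort_table):
        for f in group_kfold(cohort_table, k=3):
            assert not (f.test_participants & f.train_participants)

    def test_partition(self, cohort_table):
        assert _partition_ok(group_kfold(cohort_table, k=3), cohort_table.n_trials)

    def test_71_participants_split_24_24_23(self, cohort_table):
        """Holding one participant out, the remaining 71 split into groups of
        24/24/23 participants — so the largest inner-train split has 48."""
        pids = cohort_table.participant_ids.astype(str)
        keep = pids != cohort_table.participants[0]
        sub = cohort_table.subset(np.flatnonzero(keep))
        folds = group_kfold(sub, k=3)
        sizes = sorted(len(f.test_participants) for f in folds)
        assert sizes == [23, 24, 24]
        assert max(len(f.train_participants) for f in folds) == 48

    def test_trial_counts_balanced(self, cohort_table):
        folds = group_kfold(cohort_table, k=3)
        sizes = [len(f.test_trials) for f in folds]
        assert max(sizes) - min(sizes) <= 10  # one participant's worth

    def test_matches_sklearn_group_integrity(self, cohort_table):
        """sklearn's GroupKFold as independent oracle for the grouping
        property: our folds and theirs both keep participants atomic and
        produce balanced trial counts."""
        from sklearn.model_selection import GroupKFold

        pids = cohort_table.participant_ids.astype(str)
        ours = group_kfold(cohort_table, k=3)
        theirs = list(GroupKFold(n_splits=3).split(cohort_table.features, groups=pids))
        our_sizes = sorted(len(f.test_trials) for f in ours)
        their_sizes = sorted(len(te) for _, te in theirs)
        assert abs(our_sizes[0] - their_sizes[0]) <= 10
        for _, te in theirs:
            test_p = set(pids[te])
            train_p = set(pids) - test_p
            assert not (test_p & train_p)

    def test_too_few_participants_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="participants"):
            group_kfold(tiny_table, k=3)

    def test_deterministic(self, cohort_table):
        a = group_kfold(cohort_table, k=3)
        b = group_kfold(cohort_table, k=3)
        assert all(np.array_equal(x.test_trials, y.test_trials) for x, y in zip(a, b))


class TestLopo:
    def test_72_participants_give_72_folds(self, cohort_table):
        assert len(lopo(cohort_table)) == 72

    def test_two_participants_complementary(self, tiny_table):
        folds = lopo(tiny_table)
        assert len(folds) == 2
        assert set(folds[0].test_trials.tolist()) == set(folds[1].train_trials.tolist())

    def test_partition(self, cohort_table):
        assert _partition_ok(lopo(cohort_table), cohort_table.n_trials)

    def test_fold_order_ascending_participant(self, cohort_table):
        folds = lopo(cohort_table)
        held_out = [next(iter(f.test_participants)) for f in folds]
        assert held_out == sorted(held_out)

    def test_single_participant_rejected(self):
        t = TrialTable(
            features=np.zeros((3, 1)),
            labels=np.array([1, 1, 1]),
            participant_ids=np.array(["A", "A", "A"], dtype=object),
            trial_indices=np.array([1, 2, 3]),
        )
        with pytest.raises(ValueError, match="2 participants"):
            lopo(t)


class TestNestedPlan:
    def test_72_by_3_structure(self, cohort_table):
        plan = nested_plan(cohort_table, inner_k=3)
        assert len(plan.outer) == 72
        assert sum(len(inner) for inner in plan.inner) == 216

    def test_outer_test_participant_never_in_inner_splits(self, cohort_table):
        plan = nested_plan(cohort_table, inner_k=3)
        pids = cohort_table.participant_ids.astype(str)
        for ofold, inner in zip(plan.outer, plan.inner):
            held = ofold.test_participants
            for ifold in inner:
                assert not (held & set(pids[ifold.train_trials]))
                assert not (held & set(pids[ifold.test_trials]))

    def test_inner_validation_is_whole_participants(self, cohort_table):
        plan = nested_plan(cohort_table, inner_k=3)
        pids = cohort_table.participant_ids.astype(str)
        for ofold, inner in zip(plan.outer[:5], plan.inner[:5]):
            for ifold in inner:
                val_p = set(pids[ifold.test_trials])
                # every trial of a validation participant is in the split
                for p in val_p:
                    rows_of_p = set(np.flatnonzero(pids == p).tolist())
                    assert rows_of_p <= set(ifold.test_trials.tolist())

    def test_four_participants_forced_singletons(self):
        t = generate_feature_table(
            GeneratorConfig(n_participants=4, n_high_fear=2, seed=0)
        )
        plan = nested_plan(t, inner_k=3)
        for inner in plan.inner:
            assert sorted(len(f.test_participants) for f in inner) == [1, 1, 1]

    def test_too_few_participants_names_minimum(self):
        t = generate_feature_table(
            GeneratorConfig(n_participants=3, n_high_fear=1, seed=0)
        )
        with pytest.raises(ValueError, match="4"):
            nested_plan(t, inner_k=3)


def test_greedy_assignment_is_trial_balanced_lpt():
    """The greedy rule equals a brute-force LPT re-implementation."""
    rng = np.random.default_rng(0)
    counts = dict(zip([f"P{i:02d}" for i in range(20)], rng.integers(5, 11, 20)))
    groups = np.concatenate([[p] * c for p, c in counts.items()])
    fold_of = ParticipantGroupKFold(n_splits=3).group_assignment(groups)
    # oracle: sort by count desc then id, assign to least-loaded fold
    loads = [0, 0, 0]
    expect = {}
    for p in sorted(counts, key=lambda p: (-counts[p], p)):
        f = loads.index(min(loads))
        expect[p] = f
        loads[f] += counts[p]
    assert fold_of == expect
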