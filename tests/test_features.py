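import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacv import (
    GeneratorConfig,
    STAT_DESCRIPTORS,
    TrialTable,
    apply_scaler,
    fdr_filter,
    fit_scaler,
    generate_feature_table,
    generate_raw_signals,
    rank_importance,
    select_top_k,
    summarize_signals,
)
from pacv.features import features_from_signals
from pacv.synthetic import RawTrialSignals


def _trial(signals, names=None):
    return RawTrialSignals(
        participant_id="P1", trial_index=1, label=0,
        signals=np.asarray(signals, dtype=float),
        signal_names=names or [],
    )


class TestSummarizeSignals:
    @pytest.mark.parametrize("n_signals", [1, 4, 48])
    def test_feature_count_is_13_per_signal(self, n_signals):
        sig = np.tile(np.sin(np.linspace(0, 5, 101)), (n_signals, 1))
        values, names = summarize_signals(_trial(sig))
        assert len(values) == len(names) == n_signals * 13

    def test_constant_signal_degenerate_conventions(self):
        values, names = summarize_signals(_trial([[5.0, 5.0, 5.0, 5.0]]))
        got = dict(zip(names, values))
        for stat in ("sd", "variance", "skewness", "kurtosis", "abs_sum_of_changes",
                     "count_above_mean", "count_below_mean",
                     "autocorr_lag1", "autocorr_lag2"):
            assert got[f"signal_00__{stat}"] == 0.0
        assert got["signal_00__mean"] == 5.0

    def test_hand_computed_descriptors(self):
        values, names = summarize_signals(_trial([[1.0, 2.0, 3.0, 4.0]]))
        got = dict(zip(names, values))
        assert got["signal_00__mean"] == 2.5
        assert got["signal_00__p50"] == 2.5
        assert got["signal_00__abs_sum_of_changes"] == 3.0
        assert got["signal_00__count_above_mean"] == 2.0
        assert got["signal_00__count_below_mean"] == 2.0
        assert got["signal_00__sd"] == pytest.approx(np.sqrt(1.25))
        assert got["signal_00__variance"] == pytest.approx(1.25)
        assert got["signal_00__p10"] == pytest.approx(1.3)
        assert got["signal_00__p90"] == pytest.approx(3.7)

    def test_autocorr_matches_definition(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        values, names = summarize_signals(_trial([x]))
        got = dict(zip(names, values))
        xc = x - x.mean()
        for lag in (1, 2):
            expected = np.dot(xc[:-lag], xc[lag:]) / np.dot(xc, xc)
            assert got[f"signal_00__autocorr_lag{lag}"] == pytest.approx(expected)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="lag-2"):
            summarize_signals(_trial([[1.0, 2.0]]))

    def test_names_follow_signal_order_not_content(self):
        a = np.linspace(0, 1, 10)
        b = np.cos(np.linspace(0, 2, 10))
        v1, n1 = summarize_signals(_trial([a, b], names=["s1", "s2"]))
        v2, n2 = summarize_signals(_trial([b, a], names=["s2", "s1"]))
        assert dict(zip(n1, v1)) == dict(zip(n2, v2))

    def test_cohort_pipeline_yields_624_features(self):
        cfg = GeneratorConfig(seed=3, n_participants=4, n_high_fear=2, n_signals=48,
                              trials_min=2, trials_max=3)
        table = features_from_signals(generate_raw_signals(cfg))
        assert table.n_features == 624
        assert len(STAT_DESCRIPTORS) == 13


def _bh_bruteforce(pvals, alpha):
    """Largest k with p_(k) <= alpha*k/m; retain everything at or below p_(k)."""
    m = len(pvals)
    order = np.argsort(pvals)
    keep = np.zeros(m, dtype=bool)
    kmax = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= alpha * rank / m:
            kmax = rank
    if kmax:
        keep[order[:kmax]] = True
    return keep


class TestFdrFilter:
    def _table_from_pvals_shape(self, n=40, d=6, seed=0):
        rng = np.random.default_rng(seed)
        return TrialTable(
            features=rng.normal(size=(n, d)),
            labels=np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)],
            participant_ids=np.array([f"P{i}" for i in range(n)], dtype=object),
            trial_indices=np.ones(n, int),
        )

    def test_single_class_rejected(self):
        t = self._table_from_pvals_shape()
        t.labels = np.zeros(t.n_trials, int)
        with pytest.raises(ValueError, match="class"):
            fdr_filter(t)

    def test_perfect_separator_retained(self):
        t = self._table_from_pvals_shape(n=60)
        t.features[:, 0] = t.labels
        res = fdr_filter(t)
        assert res.retained[0]
        assert res.p_values[0] < 1e-6

    def test_zero_variance_feature_gets_p_one(self):
        t = self._table_from_pvals_shape()
        t.features[:, 2] = 3.14
        res = fdr_filter(t)
        assert res.p_values[2] == 1.0 and not res.retained[2]

    def test_bh_matches_bruteforce_oracle(self):
        """fdr_filter's retained set equals the textbook step-up rule applied
        to the p-values it reports, across randomized tables."""
        for seed in range(12):
            rng = np.random.default_rng(seed)
            d = int(rng.integers(2, 60))
            t = self._table_from_pvals_shape(n=50, d=d, seed=seed)
            # plant a few real effects so retention is non-trivial
            for j in range(min(3, d)):
                t.features[:, j] += t.labels * rng.uniform(0.5, 2.0)
            res = fdr_filter(t, alpha=0.05)
            assert np.array_equal(res.retained, _bh_bruteforce(res.p_values, 0.05))

    def test_bh_rule_on_long_random_pvectors(self):
        """The BH backend agrees with brute force up to 1000 hypotheses."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for _ in range(10):
            m = int(rng.integers(1, 1000))
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
            got = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(got, _bh_bruteforce(p, 0.05))

    def test_spec_example_bh_threshold(self):
        p = np.array([0.001, 0.02, 0.04, 0.5])
        keep = _bh_bruteforce(p, 0.05)
        # largest k with p_(k) <= 0.05*k/4 is k=2
        assert list(keep) == [True, True, False, False]

    def test_null_retained_fraction_below_alpha(self):
        """Pure-noise features against random labels: FDR holds on average."""
        rng = np.random.default_rng(0)
        fractions = []
        for seed in range(30):
            t = self._table_from_pvals_shape(n=40, d=20, seed=seed)
            rng.shuffle(t.labels)
            res = fdr_filter(t, alpha=0.05)
            fractions.append(res.retained.mean())
        assert np.mean(fractions) <= 0.05


class TestRankImportance:
    def test_informative_feature_ranked_first(self):
        cfg = GeneratorConfig(seed=9, n_features=10, n_informative=1, class_effect=3.0,
                              participant_sd=0.1, noise_sd=1.0)
        t = generate_feature_table(cfg)
        res = rank_importance(t, seed=42)
        assert res.ranking[0] == "f0"

    def test_deterministic(self, cohort_table):
        small = cohort_table.subset(np.arange(100))
        a = rank_importance(small, seed=42)
        b = rank_importance(small, seed=42)
        assert a.ranking == b.ranking

    def test_single_retained_feature(self, cohort_table):
        mask = np.zeros(cohort_table.n_features, dtype=bool)
        mask[0] = True
        res = rank_importance(cohort_table, retained=mask, seed=42)
        assert res.ranking == ["f0"]
        assert res.importance["f0"] == pytest.approx(1.0)

    def test_empty_selection_rejected(self, cohort_table):
        with pytest.raises(ValueError, match="retained"):
            rank_importance(cohort_table, retained=np.zeros(10, dtype=bool))


class TestSelectTopK:
    def test_first_k_order_preserved(self):
        ranking = [f"f{i}" for i in range(40)]
        assert select_top_k(ranking, 10) == ranking[:10]

    def test_truncates_to_available(self):
        assert select_top_k(["a", "b", "c"], 10) == ["a", "b", "c"]

    def test_k1(self):
        assert select_top_k(["a", "b"], 1) == ["a"]

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            select_top_k(["a"], 0)


class TestScaler:
    def test_arithmetic(self):
        params = fit_scaler(np.array([[0.0], [2.0]]))
        assert params.mean[0] == 1.0 and params.sd[0] == 1.0
        assert apply_scaler(params, np.array([[3.0]]))[0, 0] == 2.0

    def test_standardized_input_unchanged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(50, 3))
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        out = apply_scaler(fit_scaler(x), x)
        assert np.max(np.abs(out - x)) < 1e-12

    def test_constant_column_maps_to_zero(self):
        params = fit_scaler(np.full((5, 1), 7.0))
        assert apply_scaler(params, np.array([[123.0]]))[0, 0] == 0.0

    def test_matches_sklearn_on_nondegenerate_columns(self):
        from sklearn.preprocessing import StandardScaler

        rng = np.random.default_rng(5)
        train, test = rng.normal(size=(30, 4)), rng.normal(size=(10, 4))
        ours = apply_scaler(fit_scaler(train), test)
        theirs = StandardScaler().fit(train).transform(test)
        assert np.allclose(ours, theirs)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            fit_scaler(np.empty((0, 3)))

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 1000), shift=st.floats(0.5, 5.0))
    def test_test_side_never_influences_fit(self, seed, shift):
        """Scaled test values change iff the train split changes."""
        rng = np.random.default_rng(seed)
        train = rng.normal(size=(20, 2))
        test = rng.normal(size=(5, 2))
        p1 = fit_scaler(train)
        p2 = fit_scaler(train)  # same train, perturbed test is irrelevant
        assert np.array_equal(apply_scaler(p1, test), apply_scaler(p2, test + 0 * shift))
        p3 = fit_scaler(train + shift)
        assert not np.array_equal(apply_scaler(p1, test), apply_scaler(p3, test))
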