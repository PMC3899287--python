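"""Classifier evaluation metrics, cross-validation, IFS sweep and feature
categorization."""

import numpy as np
import pytest

from aptapair import (
    ClassifierConfig,
    ConfusionCounts,
    IFSRecord,
    categorize_features,
    compute_metrics,
    crossvalidate,
    evaluate_holdout,
    run_ifs,
    select_optimal,
)
from aptapair.dataset import FEATURE_CATEGORIES, feature_category
from aptapair.errors import StratificationError, ValidationError


class TestComputeMetrics:
    def test_pooled_confusion_of_one_in_three_holdout(self):
        """145 positives / 435 negatives with TP=70, FP=56, TN=379, FN=75
        give Sn=0.4828, Sp=0.8713, Ac=0.7741, MCC=0.3717 to 4 d.p."""
        m = compute_metrics(ConfusionCounts(tp=70, fp=56, tn=379, fn=75))
        assert round(m.sn, 4) == 0.4828
        assert round(m.sp, 4) == 0.8713
        assert round(m.ac, 4) == 0.7741
        assert round(m.mcc, 4) == 0.3717

    def test_perfect_prediction(self):
        m = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=30, fn=0))
        assert m == (1, 1, 1, 1)

    def test_all_negative_predictor_on_one_to_three_data(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=30, fn=10))
        assert (m.sn, m.sp, m.ac, m.mcc) == (0, 1, 0.75, 0)

    def test_accuracy_identity_on_random_counts(self, rng):
        # Ac == (Sn*P + Sp*N) / (P+N) for class sizes P, N
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 200, 4)
            m = compute_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            p, n = tp + fn, tn + fp
            assert m.ac == pytest.approx((m.sn * p + m.sp * n) / (p + n), abs=1e-12)

    def test_empty_evaluation_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))


def _separable_data(n=100, n_features=5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, n_features))
    y = (X[:, 0] > 0.5).astype(int)
    return X, y


class TestCrossvalidate:
    def test_every_sample_tested_exactly_once(self):
        X, y = _separable_data(100)
        cc = crossvalidate(X, y, list(range(5)))
        assert cc.total == 100

    def test_separable_fixture_reaches_mcc_one(self):
        X, y = _separable_data(200)
        cc = crossvalidate(X, y, [0])
        assert compute_metrics(cc).mcc == 1

    def test_same_seed_identical_counts(self):
        rng = np.random.default_rng(1)
        X = rng.random((80, 6))
        y = rng.integers(0, 2, 80)
        config = ClassifierConfig(seed=9)
        assert crossvalidate(X, y, [0, 2, 4], config) == crossvalidate(
            X, y, [0, 2, 4], config
        )

    def test_class_smaller_than_fold_count_rejected(self):
        X = np.random.default_rng(0).random((20, 3))
        y = np.array([1] * 5 + [0] * 15)
        with pytest.raises(StratificationError):
            crossvalidate(X, y, [0], ClassifierConfig(folds=10))


class TestRunIfs:
    def test_one_record_per_subset_size(self):
        X, y = _separable_data(60, n_features=4)
        records = run_ifs(X, y, [0, 1, 2, 3], ClassifierConfig(folds=5))
        assert [r.k for r in records] == [1, 2, 3, 4]

    def test_single_feature_ranking(self):
        X, y = _separable_data(60, n_features=1)
        records = run_ifs(X, y, [0], ClassifierConfig(folds=5))
        assert len(records) == 1 and records[0].k == 1

    def test_k_values_restrict_the_sweep(self):
        X, y = _separable_data(60, n_features=6)
        records = run_ifs(X, y, list(range(6)), ClassifierConfig(folds=5), k_values=[1, 3, 6])
        assert [r.k for r in records] == [1, 3, 6]

    def test_duplicate_ranking_rejected(self):
        X, y = _separable_data(30, n_features=3)
        with pytest.raises(ValidationError):
            run_ifs(X, y, [0, 0, 1], ClassifierConfig(folds=5))


class TestSelectOptimal:
    def _rec(self, k, mcc):
        return IFSRecord(k=k, sn=0, sp=0, ac=0, mcc=mcc)

    def test_unique_maximum(self):
        table = [self._rec(1, 0.2), self._rec(2, 0.8), self._rec(3, 0.5)]
        assert select_optimal(table).k == 2

    def test_tie_resolves_to_smaller_k(self):
        table = [self._rec(120, 0.7), self._rec(50, 0.7), self._rec(10, 0.3)]
        assert select_optimal(table).k == 50

    def test_permutation_invariant(self, rng):
        table = [self._rec(int(k), float(m)) for k, m in
                 zip(rng.permutation(20) + 1, rng.random(20))]
        shuffled = [table[i] for i in rng.permutation(len(table))]
        assert select_optimal(table) == select_optimal(shuffled)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            select_optimal([])


class TestEvaluateHoldout:
    def test_separable_fixture_scores_perfectly_on_itself(self):
        X, y = _separable_data(120)
        _, m = evaluate_holdout(X, y, X, y, [0])
        assert m.ac == 1

    def test_same_seed_identical_metrics(self):
        rng = np.random.default_rng(2)
        X1, y1 = rng.random((80, 5)), rng.integers(0, 2, 80)
        X2, y2 = rng.random((40, 5)), rng.integers(0, 2, 40)
        config = ClassifierConfig(seed=4)
        assert evaluate_holdout(X1, y1, X2, y2, [0, 1], config) == evaluate_holdout(
            X1, y1, X2, y2, [0, 1], config
        )

    def test_informative_subset_beats_random_subset(self):
        """Across 20 seeded draws, the planted-informative feature subset
        yields strictly larger holdout MCC than an equally-sized noise
        subset in at least 95% of them."""
        wins = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            n, k = 300, 20
            X = rng.random((n, k))
            signal = X[:, :5].sum(axis=1)
            y = (signal > np.median(signal)).astype(int)
            split = n * 2 // 3
            config = ClassifierConfig(seed=seed)
            _, m_inf = evaluate_holdout(
                X[:split], y[:split], X[split:], y[split:], [0, 1, 2, 3, 4], config
            )
            _, m_rnd = evaluate_holdout(
                X[:split], y[:split], X[split:], y[split:], [10, 11, 12, 13, 14], config
            )
            wins += m_inf.mcc > m_rnd.mcc
        assert wins >= 0.95 * n_runs

    def test_out_of_range_subset_rejected(self):
        X, y = _separable_data(30)
        with pytest.raises(IndexError):
            evaluate_holdout(X, y, X, y, [99])


class TestCategorizeFeatures:
    def test_full_feature_set_layout(self):
        counts = categorize_features(range(290))
        assert tuple(counts[c] for c in FEATURE_CATEGORIES) == (
            20, 20, 50, 50, 50, 50, 50,
        )

    def test_aptamer_block_only(self):
        counts = categorize_features(range(20))
        assert counts["aptamer frequency"] == 20
        assert sum(counts.values()) == 20

    def test_random_subset_matches_per_index_scan(self, rng):
        subset = rng.choice(290, size=100, replace=False).tolist()
        counts = categorize_features(subset)
        oracle = {cat: 0 for cat in FEATURE_CATEGORIES}
        for idx in subset:
            oracle[feature_category(idx)] += 1
        assert counts == oracle
        assert sum(counts.values()) == 100

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            categorize_features([290])


def test_ifs_optimum_tracks_planted_feature_count(recovery_runs):
    """The cross-validated optimum stays near the planted feature count:
    never below it, and within planted + 15 in the large majority of the
    seeded planted-signal runs (the MCC curve saturates once the planted
    columns are in, so later optima are plateau noise, not signal)."""
    hits = 0
    for run in recovery_runs:
        lo = len(run.informative)
        assert run.optimal_k >= lo
        hits += run.optimal_k <= lo + 15
    assert hits >= 0.75 * len(recovery_runs)
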