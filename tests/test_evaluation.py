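import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pathologit as pl
from conftest import brute_force_pr_auc, pair_count_auc


class TestMcc:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((50, 0, 50, 0), 1.0),
            ((25, 25, 25, 25), 0.0),
            ((90, 20, 80, 10), 7000 / np.sqrt(110 * 100 * 100 * 90)),
            ((0, 0, 10, 10), 0.0),  # zero marginal
        ],
    )
    def test_values(self, counts, expected):
        assert pl.mcc(*counts) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.integers(0, 200), min_size=4, max_size=4))
    def test_symmetry_under_class_swap(self, counts):
        tp, fp, tn, fn = counts
        assert pl.mcc(tp, fp, tn, fn) == pytest.approx(pl.mcc(tn, fn, tp, fp), abs=1e-12)

    def test_confusion_counts_container(self):
        c = pl.ConfusionCounts(tp=1, fp=0, tn=2, fn=1)
        assert c.sensitivity == 0.5 and c.specificity == 1.0 and c.total == 4
        with pytest.raises(ValueError):
            pl.ConfusionCounts(-1, 0, 0, 0)


class TestSweep:
    def test_four_point_toy_enumeration(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.6, 0.8, 0.7])
        sweep = pl.sweep_cutoffs(labels, scores, np.array([0.0, 0.85, 1.0]))
        # cutoff 0.85: only the 0.9 positive is called
        assert (sweep.tp[1], sweep.fp[1], sweep.tn[1], sweep.fn[1]) == (1, 0, 2, 1)
        # cutoff 0: everything called positive
        assert sweep.sensitivity[0] == 1.0 and sweep.specificity[0] == 0.0

    def test_scores_equal_labels_are_perfect(self):
        labels = np.array([0, 1, 0, 1])
        sweep = pl.sweep_cutoffs(labels, labels.astype(float))
        interior = (sweep.grid > 0) & (sweep.grid <= 1.0)
        assert np.all(sweep.sensitivity[interior] == 1.0)
        assert np.all(sweep.specificity[interior] == 1.0)

    def test_optimal_cutoff_is_smallest_maximizer(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        cutoff, best = pl.sweep_cutoffs(labels, scores).optimal_cutoff()
        assert best == 1.0
        # every cutoff in (0.2, 0.8] separates perfectly; the grid's first
        # maximizer just above 0.2 is returned
        assert cutoff == pytest.approx(0.201, abs=1e-9)


class TestRocAuc:
    def test_toy_pair_counting(self):
        labels = [1, 1, 0, 0]
        scores = [0.9, 0.6, 0.8, 0.7]
        assert pl.roc_auc_from_scores(labels, scores) == pytest.approx(0.5)

    def test_constant_scores_are_chance(self):
        assert pl.roc_auc_from_scores([1, 0, 1, 0], [0.5] * 4) == pytest.approx(0.5)

    def test_separated_scores_are_perfect(self):
        assert pl.roc_auc_from_scores([1, 1, 0], [0.9, 0.8, 0.1]) == 1.0

    def test_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = rng.integers(0, 2, 60)
            if labels.sum() in (0, 60):
                continue
            scores = rng.choice(np.linspace(0, 1, 17), 60)  # heavy ties
            assert pl.roc_auc_from_scores(labels, scores) == pytest.approx(
                pair_count_auc(labels, scores), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 200)
        scores = rng.random(200)
        assert pl.roc_auc_from_scores(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 100)
        scores = rng.random(100)
        warped = 1 / (1 + np.exp(-(5 * scores - 2)))
        assert pl.roc_auc_from_scores(labels, scores) == pytest.approx(
            pl.roc_auc_from_scores(labels, warped), abs=1e-12
        )


class TestPrAuc:
    def test_perfect_classifier(self):
        assert pl.pr_auc_from_scores([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == pytest.approx(1.0)

    def test_toy_brute_force(self):
        labels = [1, 1, 0, 0]
        scores = [0.9, 0.6, 0.8, 0.7]
        assert pl.pr_auc_from_scores(labels, scores) == pytest.approx(
            brute_force_pr_auc(labels, scores), abs=1e-6
        )

    def test_random_scores_approach_class_balance(self):
        rng = np.random.default_rng(3)
        labels = (rng.random(20000) < 0.3).astype(int)
        scores = rng.random(20000)
        assert pl.pr_auc_from_scores(labels, scores) == pytest.approx(0.3, abs=0.02)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 80)
        scores = rng.random(80)
        assert pl.pr_auc_from_scores(labels, scores) == pytest.approx(
            pl.pr_auc_from_scores(labels, scores**3), abs=1e-12
        )

    def test_requires_positives(self):
        with pytest.raises(ValueError):
            pl.pr_auc_from_scores([0, 0], [0.5, 0.4])


class TestKfold:
    def test_stratification_balance(self):
        labels = np.array([1] * 50 + [0] * 50)
        folds = pl.kfold_split(labels, 10, seed=0)
        for fold in folds:
            assert labels[fold].sum() == 5 and len(fold) == 10

    def test_deterministic_partition(self):
        labels = np.array([1] * 30 + [0] * 70)
        a = pl.kfold_split(labels, 5, seed=3)
        b = pl.kfold_split(labels, 5, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        union = np.sort(np.concatenate(a))
        assert np.array_equal(union, np.arange(100))  # partition: disjoint + exhaustive

    def test_k_exceeding_size_rejected(self):
        with pytest.raises(ValueError):
            pl.kfold_split(np.array([0, 1, 0]), 4, seed=0)


class TestCrossValidate:
    def test_perfect_single_tool(self):
        dataset = pl.generate_benchmark(pl.GeneratorConfig.separable(100, 100, seed=5))
        res = pl.cross_validate(dataset, method="SIFT", K=5, seed=0)
        assert res.roc_auc == pytest.approx(1.0, abs=1e-12)
        assert res.pr_auc == pytest.approx(1.0, abs=1e-9)
        assert res.max_mcc_test == pytest.approx(1.0)  # every test sweep separates
        # the train-selected cutoff can sit at the class edge, so the deployed
        # MCC may dip just below 1 on a held-out fold
        assert res.max_mcc > 0.9

    def test_combined_beats_weak_pair(self, signal_benchmark):
        """Combining all five tools outperforms the conservation-only pair."""
        full = pl.cross_validate(signal_benchmark, "logit", K=5, seed=1)
        weak = pl.cross_validate(signal_benchmark, "logit", tools=("PhyloP", "LRT"), K=5, seed=1)
        assert full.roc_auc > weak.roc_auc

    def test_fold_average_lies_in_fold_hull(self, signal_benchmark):
        """Rebuild the per-fold curves from the public pieces and check the
        averaged curve stays inside their pointwise envelope."""
        tools = ("SIFT", "MutationTaster")
        res = pl.cross_validate(signal_benchmark, "logit", tools=tools, K=4, seed=2)
        subset = signal_benchmark.complete_cases(tools)
        folds = pl.kfold_split(subset, 4, seed=2)
        fold_sens = []
        all_idx = np.arange(len(subset))
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            train = pl.BenchmarkDataset(subset.frame.iloc[train_idx].reset_index(drop=True))
            test = pl.BenchmarkDataset(subset.frame.iloc[test_idx].reset_index(drop=True))
            model = pl.fit_logit(train, tools)
            sweep = pl.sweep_cutoffs(test.labels, pl.predict_posterior(model, test.frame), res.grid)
            fold_sens.append(sweep.sensitivity)
        fold_sens = np.array(fold_sens)
        assert np.all(res.sensitivity >= fold_sens.min(axis=0) - 1e-12)
        assert np.all(res.sensitivity <= fold_sens.max(axis=0) + 1e-12)
        # averaged curves are monotone in the cutoff
        assert np.all(np.diff(res.sensitivity) <= 1e-12)
        assert np.all(np.diff(res.specificity) >= -1e-12)

    def test_metrics_schema(self, signal_benchmark):
        res = pl.cross_validate(signal_benchmark, "logit", tools=("SIFT", "MutationTaster"), K=3, seed=0)
        payload = res.metrics()
        for key in ("roc_auc", "pr_auc", "max_mcc", "max_mcc_test", "optimal_cutoff", "fold_cutoffs"):
            assert key in payload
        assert 0 <= payload["roc_auc"] <= 1 and -1 <= payload["max_mcc"] <= 1
        assert len(payload["fold_cutoffs"]) == 3


class TestMannWhitney:
    def test_complete_dominance(self):
        u, p = pl.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0 and p < 0.2

    def test_identical_samples(self):
        u, p = pl.mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_exact_enumeration_small_sample(self):
        """For a={1,3}, b={2,4}: U=1; the exact two-sided p enumerates all
        C(4,2)=6 label arrangements, of which 4 are at least as extreme."""
        u, p = pl.mann_whitney([1, 3], [2, 4])
        assert u == 1.0
        # enumeration oracle over all splits of ranks {1,2,3,4}
        from itertools import combinations

        pooled = [1, 2, 3, 4]
        u_all = []
        for a_idx in combinations(range(4), 2):
            a = [pooled[i] for i in a_idx]
            b = [pooled[i] for i in range(4) if i not in a_idx]
            u_all.append(sum(x > y for x in a for y in b))
        u_all = np.array(u_all)
        p_exact = 2 * min((u_all <= 1).mean(), (u_all >= 1).mean())
        assert p == pytest.approx(min(1.0, p_exact), abs=1e-12)

    def test_matches_scipy_large_sample(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 50), rng.normal(0.5, 1, 60)
        u, p = pl.mann_whitney(a, b)
        import scipy.stats

        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
        assert u == ref.statistic and p == ref.pvalue

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            pl.mann_whitney([], [1.0])


class TestBenchmarkComparison:
    def test_computes_both_methods_and_deltas(self, signal_benchmark):
        out = pl.benchmark_comparison(
            signal_benchmark,
            K=3,
            seed=0,
            expected={"logit.max_mcc": 0.6, "condel.max_mcc": 0.55},
        )
        assert set(out) == {"logit", "condel", "deltas"}
        assert out["deltas"]["logit.max_mcc"] == pytest.approx(out["logit"]["max_mcc"] - 0.6)
        assert out["logit"]["roc_auc"] > 0.5
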