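"""Repeated double cross-validation, fold construction, permutation nulls."""
import numpy as np
import pytest

from argmet import (
    FoldScheme,
    RDCVResult,
    SingleClassFoldError,
    empirical_p,
    inner_select_nlv,
    make_cancelation_groups,
    overall_from_per_class,
    permutation_test,
    run_rdcv,
    variable_significance,
)

SMALL = FoldScheme(outer_k=5, inner_k=3, repetitions=5, seed=3,
                   candidate_lvs=(1, 2, 3))


class TestCancelationGroups:
    def test_imbalanced_study_layout(self):
        # 46 cases / 11 controls into 10 groups: 4-5 cases, 1-2 controls each
        y = np.repeat([1, 0], [46, 11])
        folds = make_cancelation_groups(y, 10, np.random.default_rng(0))
        for f in range(10):
            n1 = ((folds == f) & (y == 1)).sum()
            n0 = ((folds == f) & (y == 0)).sum()
            assert n1 in (4, 5)
            assert n0 in (1, 2)
        assert np.bincount(folds).sum() == 57

    def test_k_equals_n_is_leave_one_out(self):
        y = np.repeat([0, 1], 5)
        folds = make_cancelation_groups(y, 10, np.random.default_rng(1))
        assert sorted(folds) == list(range(10))

    def test_same_seed_reproduces_folds(self):
        y = np.repeat([1, 0], [46, 11])
        f1 = make_cancelation_groups(y, 10, np.random.default_rng(5))
        f2 = make_cancelation_groups(y, 10, np.random.default_rng(5))
        assert np.array_equal(f1, f2)

    @pytest.mark.parametrize("k", [1, 0, 58])
    def test_invalid_k_rejected(self, k):
        y = np.repeat([1, 0], [46, 11])
        with pytest.raises(ValueError):
            make_cancelation_groups(y, k, np.random.default_rng(0))


class TestInnerSelection:
    def test_single_candidate_returned(self, rng):
        X = rng.standard_normal((30, 6))
        y = np.repeat([0, 1], 15)
        assert inner_select_nlv(X, y, 3, candidate_lvs=(4,), rng=rng) == 4

    def test_single_class_rejected(self, rng):
        with pytest.raises(SingleClassFoldError):
            inner_select_nlv(rng.standard_normal((10, 6)), np.zeros(10), 3)

    def test_one_informative_variable_selects_small_complexity(self):
        # strong separation on one of six variables: the inner loop should
        # settle on <= 2 latent variables in nearly every seeded run
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 6))
            y = np.repeat([0, 1], 20)
            X[:, 0] += 10.0 * y
            if inner_select_nlv(X, y, 8, rng=rng) <= 2:
                hits += 1
        assert hits >= 45  # >= 90% of 50 runs

    def test_pure_noise_accuracy_near_majority_rate(self):
        # with y independent of X, selection gains nothing: the double-CV
        # accuracy should sit near the empirical chance level
        rng = np.random.default_rng(11)
        X = rng.standard_normal((57, 6))
        y = np.repeat([1, 0], [46, 11])
        scheme = FoldScheme(outer_k=10, inner_k=8, repetitions=10, seed=11)
        res = run_rdcv(X, y, scheme)
        # empirical chance level oracle: single passes on permuted labels
        nulls = [run_rdcv(X, np.random.default_rng(100 + i).permutation(y),
                          FoldScheme(outer_k=10, inner_k=8, repetitions=1,
                                     seed=100 + i)).accuracy_mean
                 for i in range(30)]
        nulls = np.asarray(nulls)
        assert abs(res.accuracy_mean - nulls.mean()) < 3 * nulls.std(ddof=1)


class TestRunRdcv:
    def test_perfect_separation_saturates(self, rng):
        X = rng.standard_normal((40, 6))
        y = np.repeat([0, 1], 20)
        X[:, :3] += 10.0 * y[:, None]
        res = run_rdcv(X, y, SMALL)
        assert res.accuracy_mean == 100.0
        assert res.accuracy_sd == 0.0
        assert res.n_lv_sd <= 1.0

    def test_accuracy_identity_per_repetition(self, cohort57_xy):
        X, y = cohort57_xy
        res = run_rdcv(X, y, FoldScheme(repetitions=5, seed=2))
        for i in range(5):
            overall = overall_from_per_class(
                (res.class1_rates[i], res.class0_rates[i]),
                (res.n_class1, res.n_class0))
            assert overall == pytest.approx(res.accuracies[i], abs=1e-9)

    def test_published_rate_triples_satisfy_identity(self):
        # 78.1% of 46 cases and 88.9% of 11 controls pool to 80.2% overall;
        # 54.3% and 62.6% at 23/23 pool to 58.5%
        assert overall_from_per_class((78.1, 88.9), (46, 11)) == pytest.approx(
            80.2, abs=0.1)
        assert overall_from_per_class((54.3, 62.6), (23, 23)) == pytest.approx(
            58.5, abs=0.1)

    def test_deterministic_under_seed(self, cohort57_xy):
        X, y = cohort57_xy
        scheme = FoldScheme(repetitions=3, seed=9)
        a = run_rdcv(X, y, scheme)
        b = run_rdcv(X, y, scheme)
        assert np.array_equal(a.accuracies, b.accuracies)
        assert np.array_equal(a.weight_samples, b.weight_samples)
        assert np.array_equal(a.outer_scores, b.outer_scores)
        assert np.array_equal(a.n_lv_selected, b.n_lv_selected)

    def test_too_few_samples_rejected(self, rng):
        X = rng.standard_normal((10, 6))
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="n >= 20"):
            run_rdcv(X, y, SMALL)

    def test_monotone_in_separation(self):
        # accuracy must not decrease as group separation grows (beyond noise)
        means = []
        for sep in (0.0, 1.0, 2.0, 3.0):
            accs = []
            for seed in range(3):
                rng = np.random.default_rng(1000 + seed)
                X = rng.standard_normal((40, 6))
                y = np.repeat([0, 1], 20)
                X += sep * y[:, None] / np.sqrt(6)
                accs.append(run_rdcv(X, y, FoldScheme(
                    outer_k=5, inner_k=3, repetitions=5,
                    seed=seed)).accuracy_mean)
            means.append(np.mean(accs))
        assert all(b >= a - 6.0 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]


class TestVariableSignificance:
    @staticmethod
    def _result_with_weights(W):
        n = W.shape[0]
        return RDCVResult(
            accuracies=np.full(2, 90.0), class1_rates=np.full(2, 90.0),
            class0_rates=np.full(2, 90.0),
            n_lv_selected=np.ones((2, 2), dtype=int),
            weight_samples=W, outer_scores=np.zeros((2, 4)),
            n_class1=2, n_class0=2,
        )

    def test_constant_positive_weight_significant(self):
        W = np.tile([0.5, 0.0], (50, 1))
        W[:, 1] = np.linspace(-0.2, 0.2, 50)  # symmetric around zero
        sig = variable_significance(self._result_with_weights(W))
        assert bool(sig.loc[0, "significant"]) is True
        assert sig.loc[0, "direction"] == 1
        assert bool(sig.loc[1, "significant"]) is False

    def test_study_parameterisation_recovers_reported_pattern(self):
        # methylarginines and citrulline load positive (higher in long COVID)
        # in nearly every seeded run; arginine never loads positive
        from argmet import default_cross_sectional_cohort
        names = ("arginine", "citrulline", "ornithine", "adma", "mma", "sdma")
        pos = dict.fromkeys(names, 0)
        arg_sig_pos = 0
        arg_median_neg = 0
        runs = 25
        for seed in range(runs):
            tab = default_cross_sectional_cohort(seed)
            X = tab.matrix()
            y = (tab.labels("group") == "long_covid").astype(int)
            res = run_rdcv(X, y, FoldScheme(repetitions=10, seed=seed))
            res.feature_names = names
            sig = variable_significance(res)
            for _, row in sig.iterrows():
                if row["significant"] and row["direction"] > 0:
                    pos[row["variable"]] += 1
            arg = sig[sig["variable"] == "arginine"].iloc[0]
            arg_sig_pos += bool(arg["significant"] and arg["direction"] > 0)
            arg_median_neg += arg["weight_median"] < 0
        for name in ("citrulline", "adma", "mma", "sdma"):
            assert pos[name] >= 0.8 * runs
        assert arg_sig_pos == 0
        assert arg_median_neg > runs / 2


class TestPermutation:
    def test_empirical_p_boundaries(self):
        nulls = np.arange(1000, dtype=float)
        assert empirical_p(2000.0, nulls) == pytest.approx(1 / 1001)
        assert empirical_p(-1.0, nulls) == 1.0

    def test_too_few_permutations_rejected(self, cohort57_xy):
        X, y = cohort57_xy
        with pytest.raises(ValueError, match="non-informative"):
            permutation_test(X, y, SMALL, B=10)

    def test_separated_classes_hit_floor(self, rng):
        X = rng.standard_normal((40, 6))
        y = np.repeat([0, 1], 20)
        X[:, :3] += 10.0 * y[:, None]
        perm = permutation_test(X, y, SMALL, B=99,
                                rng=np.random.default_rng(4))
        assert perm.p_value == pytest.approx(1 / 100)
        assert perm.observed_accuracy == 100.0
        assert perm.null_accuracies.max() < 100.0
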