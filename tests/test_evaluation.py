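import numpy as np
import pytest

import cladepred as cp
from cladepred.evaluation import EvaluationRecord, empirical_pvalue


class TestNullModels:
    def test_bernoulli_all_ones_training(self):
        preds = cp.bernoulli_null_predict([1, 1, 1, 1], 10, rng_seed=0)
        assert (preds == 1).all()

    def test_bernoulli_expected_accuracy_closed_form(self):
        # train frequency p = 0.75, test all ones (q = 1): E[acc] = 0.75
        train = [1, 1, 1, 0]
        accs = [
            (cp.bernoulli_null_predict(train, 50, rng_seed=s) == 1).mean()
            for s in range(200)
        ]
        assert np.mean(accs) == pytest.approx(0.75, abs=0.02)

    def test_bernoulli_seeded_draw_is_reproducible(self):
        a = cp.bernoulli_null_predict([1, 0, 1], 20, rng_seed=7)
        b = cp.bernoulli_null_predict([1, 0, 1], 20, rng_seed=7)
        assert (a == b).all()

    @pytest.mark.parametrize("train,expected", [
        ([1, 1, 1, 0], 1), ([0, 0, 0, 0], 0), ([1, 0, 1, 0], 1)])
    def test_identity_majority_and_tie_break(self, train, expected):
        assert (cp.identity_null_predict(train, 5) == expected).all()

    def test_identity_accuracy_equals_majority_test_frequency(self):
        train = [1, 1, 0]
        test = np.array([1, 0, 0, 1, 1])
        preds = cp.identity_null_predict(train, len(test))
        assert cp.score(preds, test).accuracy == test.mean()


class TestScore:
    def test_perfect(self):
        s = cp.score([1, 0, 1], [1, 0, 1])
        assert (s.accuracy, s.balanced_accuracy) == (1.0, 1.0)

    def test_sensitivity_specificity_mean(self):
        s = cp.score([1, 1, 1, 1], [1, 1, 1, 0])
        assert s.accuracy == 0.75
        assert s.balanced_accuracy == 0.5  # sens 1, spec 0

    def test_one_class_labels_flagged(self):
        s = cp.score([1, 1], [1, 1])
        assert s.accuracy == 1.0
        assert not s.balanced_defined
        assert s.balanced_accuracy == s.accuracy

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cp.score([], [])


class TestPermutationTTest:
    def test_identical_samples_give_p_one(self):
        assert cp.permutation_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]) == 1.0

    def test_exhaustive_three_vs_three(self):
        # 20 assignments; only the 2 perfect separations reach |t| = inf
        assert cp.permutation_t_test([1, 1, 1], [0, 0, 0]) == pytest.approx(0.1)

    def test_symmetry_under_sample_swap(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 1, 6)
        # exhaustive branch (C(14,6) = 3003 assignments): exact symmetry
        p1 = cp.permutation_t_test(a, b, 5000)
        p2 = cp.permutation_t_test(b, a, 5000)
        assert p1 == p2
        # Monte-Carlo branch: symmetric up to sampling error
        p1 = cp.permutation_t_test(a, b, 2000, rng_seed=1)
        p2 = cp.permutation_t_test(b, a, 2000, rng_seed=1)
        assert p1 == pytest.approx(p2, abs=0.03)

    def test_zero_pooled_variance_gives_p_one(self):
        assert cp.permutation_t_test([1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_monte_carlo_close_to_exhaustive(self, rng):
        a = rng.normal(0, 1, 9)
        b = rng.normal(1.2, 1, 9)
        exact = cp.permutation_t_test(a, b, n_permutations=100_000)
        mc = cp.permutation_t_test(a, b, n_permutations=20_000, rng_seed=2)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_rejects_singleton_sample(self):
        with pytest.raises(ValueError):
            cp.permutation_t_test([1.0], [0.0, 0.5])


def oracle_holm_sidak(p):
    """Independent closed-form step-down Sidak."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj


class TestHolmSidak:
    def test_single_pvalue_unchanged(self):
        assert cp.holm_sidak([0.03]) == pytest.approx([0.03])

    def test_two_pvalue_closed_form(self):
        adj = cp.holm_sidak([0.01, 0.04])
        assert adj == pytest.approx([1 - 0.99**2, 0.04])

    def test_all_zero(self):
        assert cp.holm_sidak([0.0, 0.0, 0.0]) == pytest.approx([0, 0, 0])

    def test_matches_independent_oracle(self, rng):
        for _ in range(25):
            p = rng.random(rng.integers(1, 12))
            assert cp.holm_sidak(p) == pytest.approx(oracle_holm_sidak(p))

    def test_output_dominates_input_and_monotone(self, rng):
        p = rng.random(10)
        adj = cp.holm_sidak(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def _rec(trait, model, accs):
    return EvaluationRecord(trait, model, "random", list(accs), list(accs))


class TestCompareToNulls:
    def test_clear_separation_is_significant(self):
        model = [_rec("t", "rf", [1.0] * 20)]
        bern = [_rec("t", "bernoulli", [0.5, 0.52] * 10)]
        ident = [_rec("t", "identity", [0.55, 0.5] * 10)]
        res = cp.compare_to_nulls(model, bern, ident, rng_seed=0,
                                  n_permutations=2000)
        assert res[0].significant

    def test_identical_to_null_not_significant(self):
        accs = [0.5, 0.6, 0.7, 0.4] * 5
        res = cp.compare_to_nulls([_rec("t", "rf", accs)],
                                  [_rec("t", "b", accs)],
                                  [_rec("t", "i", accs)],
                                  rng_seed=0, n_permutations=2000)
        assert not res[0].significant
        assert res[0].p_vs_bernoulli == 1.0

    def test_joint_correction_over_traits(self):
        # ten traits, one strongly separated: its corrected p reflects m=10
        model, bern, ident = [], [], []
        rng = np.random.default_rng(5)
        for k in range(10):
            if k == 0:
                accs = [0.95 + 0.01 * (i % 3) for i in range(12)]
            else:
                accs = list(rng.uniform(0.45, 0.55, 12))
            model.append(_rec(f"t{k}", "rf", accs))
            bern.append(_rec(f"t{k}", "b", list(rng.uniform(0.45, 0.55, 12))))
            ident.append(_rec(f"t{k}", "i", list(rng.uniform(0.45, 0.55, 12))))
        res = cp.compare_to_nulls(model, bern, ident, rng_seed=1,
                                  n_permutations=5000)
        assert res[0].p_vs_bernoulli_corrected >= res[0].p_vs_bernoulli
        assert res[0].significant

    def test_mismatched_partition_counts_rejected(self):
        with pytest.raises(ValueError, match="partition counts"):
            cp.compare_to_nulls([_rec("t", "rf", [1, 1, 1])],
                                [_rec("t", "b", [0, 0])],
                                [_rec("t", "i", [0, 0, 0])])


class TestFixedPredictionPvalue:
    def test_strictly_greater_counting(self):
        assert empirical_pvalue(0.5, [0.2, 0.4, 0.6, 0.8]) == 0.5

    def test_observed_perfect_accuracy(self):
        y = [1] * 10 + [0] * 10
        p = cp.fixed_prediction_pvalue(1.0, "bernoulli", y,
                                       n_partitions=500, rng_seed=0)
        assert p == 0.0

    def test_observed_zero_accuracy(self):
        y = [1] * 10 + [0] * 10
        p = cp.fixed_prediction_pvalue(0.0, "identity", y,
                                       n_partitions=500, rng_seed=0)
        # near 1: only the null draws that themselves score 0 don't count
        assert p > 0.9

    def test_plus_one_guard(self):
        assert empirical_pvalue(1.0, [0.5, 0.5], plus_one=True) == pytest.approx(1 / 3)
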