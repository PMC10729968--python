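import numpy as np
import pandas as pd
import pytest

import cladepred as cp


def two_clade_tree():
    """Two tight 3-leaf clades separated by a long internal branch."""
    newick = ("((A:0.01,(B:0.01,C:0.01):0.01):0.5,"
              "(D:0.01,(E:0.01,F:0.01):0.01):0.5);")
    return cp.PhyloTree.from_newick(newick)


class TestTraitDifferenceCurve:
    def test_constant_trait_is_zero(self):
        tree = two_clade_tree()
        dist = tree.patristic_matrix()
        y = pd.Series(1, index=dist.strain_ids)
        curve = cp.trait_difference_curve(dist, y, rng_seed=0, n_bootstrap=5)
        assert np.nanmax(curve.mean_difference) == 0.0

    def test_random_balanced_trait_approaches_half(self, rng):
        tree = cp.simulate_tree(60, rng_seed=21)
        dist = tree.patristic_matrix()
        # expectation at large d for a shuffled balanced trait: 2p(1-p) = 0.5
        vals = []
        for seed in range(10):
            y = pd.Series(np.random.default_rng(seed).permutation(
                [0, 1] * 30), index=dist.strain_ids)
            curve = cp.trait_difference_curve(dist, y, rng_seed=0,
                                              n_bootstrap=2)
            vals.append(curve.mean_difference[-1])
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_two_clade_trait_matches_pair_enumeration(self):
        tree = two_clade_tree()
        dist = tree.patristic_matrix()
        y = pd.Series([0, 0, 0, 1, 1, 1],
                      index=["A", "B", "C", "D", "E", "F"])
        grid = [0.1, 2.0]
        curve = cp.trait_difference_curve(dist, y, d_grid=grid,
                                          n_bootstrap=3, rng_seed=0)
        # oracle: direct enumeration over the 15 leaf pairs
        ids = dist.strain_ids
        exp = {}
        for d in grid:
            diffs = [abs(y[a] - y[b])
                     for i, a in enumerate(ids) for b in ids[i + 1:]
                     if dist.to_frame().loc[a, b] <= d]
            exp[d] = np.mean(diffs)
        assert curve.mean_difference[0] == pytest.approx(exp[0.1])  # within clades
        assert curve.mean_difference[1] == pytest.approx(exp[2.0])
        assert curve.mean_difference[0] == 0.0
        assert curve.mean_difference[1] == pytest.approx(9 / 15)

    def test_curve_bounded(self, rng):
        tree = cp.simulate_tree(30, rng_seed=31)
        dist = tree.patristic_matrix()
        y = pd.Series(rng.integers(0, 2, 30), index=dist.strain_ids)
        curve = cp.trait_difference_curve(dist, y, n_bootstrap=2, rng_seed=0)
        vals = curve.mean_difference[~np.isnan(curve.mean_difference)]
        assert ((vals >= 0) & (vals <= 1)).all()


class TestCorrelationLength:
    def test_clade_membership_trait_detected(self):
        # 24 leaves: a tight clade against the rest, far apart
        left = "(" + ",".join(f"L{i}:0.02" for i in range(12)) + "):1.0"
        right = "(" + ",".join(f"R{i}:0.02" for i in range(12)) + "):1.0"
        tree = cp.PhyloTree.from_newick(f"({left},{right});")
        dist = tree.patristic_matrix()
        y = pd.Series([1 if s.startswith("L") else 0 for s in dist.strain_ids],
                      index=dist.strain_ids)
        res = cp.correlation_length(dist, y, window_width=0.1)
        assert res.correlation_length > 0
        # oracle: brute-force contingency for the first window
        d = dist.values[np.triu_indices(24, 1)]
        yv = y[dist.strain_ids].to_numpy()
        same = (yv[:, None] == yv[None, :])[np.triu_indices(24, 1)]
        inside = d < 0.1
        from scipy.stats import chi2_contingency
        table = [[np.sum(same & inside), np.sum(~same & inside)],
                 [np.sum(same & ~inside), np.sum(~same & ~inside)]]
        assert res.p_values[0] == pytest.approx(chi2_contingency(table).pvalue)

    def test_constant_trait_gives_zero(self):
        tree = cp.simulate_tree(20, rng_seed=41)
        dist = tree.patristic_matrix()
        y = pd.Series(1, index=dist.strain_ids)
        res = cp.correlation_length(dist, y)
        assert res.correlation_length == 0.0
        assert np.isnan(res.p_values).all()  # all windows degenerate

    def test_invariant_to_label_swap(self):
        tree = cp.simulate_tree(40, rng_seed=42)
        dist = tree.patristic_matrix()
        rng = np.random.default_rng(4)
        y = pd.Series(rng.integers(0, 2, 40), index=dist.strain_ids)
        a = cp.correlation_length(dist, y)
        b = cp.correlation_length(dist, 1 - y)
        assert a.correlation_length == b.correlation_length
        assert np.allclose(a.p_values, b.p_values, equal_nan=True)


def nn_runner(dist, y):
    def runner(part):
        labels = y.loc[part.train_ids].to_numpy()

        def predict(ids):
            return cp.nn_predict(dist, part.train_ids, labels, list(ids)
                                 ).predictions
        return predict
    return runner


@pytest.fixture(scope="module")
def setting():
    tree = cp.simulate_tree(48, rng_seed=51)
    genotypes = cp.simulate_gene_content(tree, 80, rng_seed=52)
    dist = cp.distance_matrix(genotypes, "l1")
    y = pd.Series(genotypes.values[:, 0], index=genotypes.strain_ids)
    parts = [cp.random_partition(genotypes.strain_ids, 0.2, s)
             for s in range(6)]
    return dist, y, parts


class TestNNMimicry:
    def test_nn_classifier_has_mu_zero(self, setting):
        dist, y, parts = setting
        res = cp.nn_mimicry(nn_runner(dist, y), dist, parts, rng_seed=0)
        assert (res.mu == 0).all()

    def test_constant_classifier(self, setting):
        dist, y, parts = setting

        def runner(part):
            return lambda ids: np.zeros(len(list(ids)), dtype=int)

        res = cp.nn_mimicry(runner, dist, parts, rng_seed=0)
        assert (res.mu == 0).all() and (res.mu_rand == 0).all()
        assert res.p_value == 1.0

    def test_coin_flip_classifier_expectation(self, setting):
        dist, y, parts = setting
        coin = np.random.default_rng(9)
        cache = {}

        def runner(part):
            def predict(ids):
                out = []
                for s in ids:
                    if s not in cache:
                        cache[s] = int(coin.integers(0, 2))
                    out.append(cache[s])
                return np.array(out)
            return predict

        # fresh prediction function per partition: f(x) i.i.d. fair coin
        mus = []
        for p in parts * 5:
            cache.clear()
            res = cp.nn_mimicry(runner, dist, [p], rng_seed=1)
            mus.append(res.mu[0])
        assert np.mean(mus) == pytest.approx(0.5, abs=0.1)
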