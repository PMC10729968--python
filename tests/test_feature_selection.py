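import json
from itertools import combinations

import numpy as np
import pytest

import cladepred as cp
from cladepred.feature_selection import Reaction


def oracle_entropy(X, y):
    """Direct enumeration over row groups (independent of the fast path)."""
    X = np.atleast_2d(X)
    groups = {}
    for row, label in zip(map(tuple, X), y):
        groups.setdefault(row, []).append(label)
    h = 0.0
    m = len(y)
    for labels in groups.values():
        p = np.mean(labels)
        hy = 0.0
        for q in (p, 1 - p):
            if q > 0:
                hy -= q * np.log2(q)
        h += len(labels) / m * hy
    return h


class TestConditionalEntropy:
    def test_perfect_single_gene(self):
        y = np.array([0, 1, 0, 1])
        assert cp.conditional_entropy(y.reshape(-1, 1), y) == 0.0

    def test_constant_gene_balanced_trait(self):
        y = np.array([0, 0, 1, 1])
        x = np.zeros((4, 1))
        assert cp.conditional_entropy(x, y) == pytest.approx(1.0)

    def test_uninformative_alternating_gene(self):
        y = np.array([0, 0, 1, 1])
        x = np.array([0, 1, 0, 1]).reshape(-1, 1)
        assert cp.conditional_entropy(x, y) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_instances(self, rng):
        for _ in range(60):
            m = int(rng.integers(2, 9))
            k = int(rng.integers(1, 7))
            X = (rng.random((m, k)) < 0.5).astype(int)
            y = rng.integers(0, 2, m)
            assert cp.conditional_entropy(X, y) == pytest.approx(
                oracle_entropy(X, y))

    def test_nonincreasing_when_genes_added(self, rng):
        for _ in range(20):
            X = (rng.random((12, 6)) < 0.5).astype(int)
            y = rng.integers(0, 2, 12)
            subset = sorted(rng.choice(6, size=3, replace=False))
            h_small = cp.conditional_entropy(X[:, subset[:2]], y)
            h_large = cp.conditional_entropy(X[:, subset], y)
            assert h_large <= h_small + 1e-12


def xor_design():
    """y = g1 XOR g2 over the full factorial, plus two decoy genes."""
    X = np.array([
        [0, 0, 0, 1],
        [0, 1, 0, 1],
        [1, 0, 0, 0],
        [1, 1, 1, 1],
    ])
    y = np.array([0, 1, 1, 0])
    return X, y, ["g1", "g2", "g3", "g4"]


class TestGreedyEntropySelect:
    def test_zero_entropy_single_gene_early_stop(self):
        y = np.array([0, 1, 1, 0, 1])
        X = np.column_stack([1 - y, np.zeros(5, dtype=int)])
        fs = cp.greedy_entropy_select(X, y, gene_ids=["hit", "dud"])
        assert fs.gene_ids == ["hit"]
        assert fs.achieved_score == 0.0

    def test_xor_pair_found_in_round_two(self):
        X, y, genes = xor_design()
        fs = cp.greedy_entropy_select(X, y, gene_ids=genes, k_max=5,
                                      beam_width=5)
        assert fs.gene_ids == ["g1", "g2"]
        assert fs.achieved_score == 0.0

    def test_width_one_greedy_misses_deceptive_xor(self):
        # g3 nearly encodes y, so pure greedy latches onto it; only the
        # {g1, g2} pair reaches zero entropy
        X = np.array([
            [0, 0, 1, 0],  # g3 flipped on this row
            [0, 0, 0, 0],
            [0, 1, 1, 0],
            [0, 1, 1, 0],
            [1, 0, 1, 0],
            [1, 0, 1, 0],
            [1, 1, 0, 0],
            [1, 1, 0, 0],
        ])
        y = X[:, 0] ^ X[:, 1]
        genes = ["g1", "g2", "g3", "g4"]
        exhaustive_best = min(
            cp.conditional_entropy(X[:, list(pair)], y)
            for pair in combinations(range(4), 2))
        assert exhaustive_best == 0.0
        narrow = cp.greedy_entropy_select(X, y, gene_ids=genes, k_max=2,
                                          beam_width=1)
        wide = cp.greedy_entropy_select(X, y, gene_ids=genes, k_max=2,
                                        beam_width=4)
        assert wide.achieved_score == 0.0
        assert narrow.achieved_score > 0.0  # documented greedy failure mode

    def test_k_max_caps_at_available_genes(self):
        X = np.array([[0, 1], [1, 0], [1, 1], [0, 0]])
        y = np.array([0, 1, 1, 0])
        fs = cp.greedy_entropy_select(X, y, k_max=5, beam_width=2)
        assert len(fs.gene_ids) <= 2


def stripe_tree_16():
    leaves = [f"L{i:02d}" for i in range(16)]

    def build(names):
        if len(names) == 1:
            return names[0] + ":0.1"
        half = len(names) // 2
        return f"({build(names[:half])},{build(names[half:])}):0.1"

    return cp.PhyloTree.from_newick(build(leaves) + ";"), leaves


class TestMetaLearning:
    def test_clade_conserved_gene_wins_round_one(self, rng):
        tree, leaves = stripe_tree_16()
        # g0 alternates within every cherry: all meta-splits see both classes
        g0 = np.array([0, 1] * 8)
        decoys = (rng.random((16, 6)) < 0.5).astype(int)
        X = np.column_stack([g0, decoys])
        genes = ["g0"] + [f"d{j}" for j in range(6)]
        fs, clf = cp.meta_learning_select(
            X, g0, leaves, tree, gene_ids=genes, k_max=1, n_meta=10,
            rng_seed=0)
        assert fs.gene_ids == ["g0"]
        assert fs.achieved_score == 1.0
        assert (clf.predict(X[:, [0]]) == g0).all()

    def test_shuffled_labels_near_majority_baseline(self, rng):
        tree, leaves = stripe_tree_16()
        X = (rng.random((16, 8)) < 0.5).astype(int)
        y = rng.permutation([0] * 8 + [1] * 8)
        fs, _ = cp.meta_learning_select(
            X, y, leaves, tree, gene_ids=[f"g{j}" for j in range(8)],
            k_max=2, n_meta=10, beam_width=3, rng_seed=1)
        assert fs.achieved_score <= 0.85  # no structure to exploit

    def test_deterministic_for_seed(self, rng):
        tree, leaves = stripe_tree_16()
        X = (rng.random((16, 6)) < 0.5).astype(int)
        y = np.array([0, 1] * 8)
        runs = [cp.meta_learning_select(
            X, y, leaves, tree, gene_ids=[f"g{j}" for j in range(6)],
            k_max=2, n_meta=8, rng_seed=7)[0] for _ in range(2)]
        assert runs[0] == runs[1]


@pytest.fixture(scope="module")
def expected():
    with open(cp.fixture_reaction_graph_expected_path()) as fh:
        return json.load(fh)


class TestReactionGraphSelection:
    @pytest.mark.parametrize("carbon,key,kwargs", [
        ("lactose", "pathways", {"level": "pathways"}),
        ("lactose", "reactions", {"level": "reactions"}),
        ("lactose", "paths_directed", {"level": "paths"}),
        ("lactose", "paths_undirected", {"level": "paths", "directed": False}),
        ("glycerol", "pathways", {"level": "pathways"}),
        ("glycerol", "reactions", {"level": "reactions"}),
        ("glycerol", "paths_directed", {"level": "paths"}),
        ("glucose", "pathways", {"level": "pathways"}),
        ("glucose", "reactions", {"level": "reactions"}),
        ("glucose", "paths_directed", {"level": "paths"}),
    ])
    def test_matches_hand_derived_sets(self, fixture_graph, expected,
                                       carbon, key, kwargs):
        got = cp.kegg_select(fixture_graph, carbon, **kwargs)
        assert sorted(got) == expected[carbon][key]

    def test_fewer_paths_than_requested_uses_all(self, fixture_graph):
        # glycerol has exactly two loopless paths into the destinations
        top2 = cp.kegg_select(fixture_graph, "glycerol", "paths", top_k_paths=2)
        top9 = cp.kegg_select(fixture_graph, "glycerol", "paths", top_k_paths=9)
        assert top2 == top9

    def test_reactions_subset_of_pathways_when_premise_holds(self,
                                                             fixture_graph):
        for carbon in ("lactose", "glucose"):
            rx = cp.kegg_select(fixture_graph, carbon, "reactions")
            pw = cp.kegg_select(fixture_graph, carbon, "pathways")
            assert rx <= pw

    def test_unknown_carbon_rejected(self, fixture_graph):
        with pytest.raises(ValueError, match="not in the reaction graph"):
            cp.kegg_select(fixture_graph, "unobtainium", "reactions")

    def test_unreachable_destination_warns_and_returns_empty(self):
        graph = cp.ReactionGraph(
            compounds=["a", "b", "dest"],
            reactions=[Reaction("R1", "a", "b", ["K1"])],
            pathways={}, destinations=["dest"])
        with pytest.warns(UserWarning, match="no loopless path"):
            assert cp.kegg_select(graph, "a", "paths") == set()

    def test_json_roundtrip(self, fixture_graph, tmp_path):
        out = tmp_path / "graph.json"
        fixture_graph.to_json(out)
        back = cp.ReactionGraph.from_json(out)
        assert back == fixture_graph
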