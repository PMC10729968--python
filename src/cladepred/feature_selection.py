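"""Feature selection: conditional entropy, meta-learning, reaction graph.

Three routes to a small predictive gene set:

* **Conditional entropy** — beam search for the gene subset minimizing the
  empirical conditional entropy H(y | X_subset); zero entropy means the
  training labels are a deterministic function of the selected genes.
* **Meta-learning** — the same beam search, but candidate sets are scored by
  their mean out-of-clade generalization accuracy on meta-partitions drawn
  from the training set alone (a domain-generalization criterion).
* **Reaction graph** — biochemically informed selection: given a curated
  metabolite/reaction graph, pick the gene orthologs of (1) all pathways
  containing the carbon source, (2) the reactions on the top-k shortest
  paths from the carbon source into central metabolism, or (3) only the
  reactions directly involving the carbon source.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import islice
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .dataio import PhyloTree
from .partitioning import enumerate_clade_testsets, out_of_clade_partition

__all__ = [
    "FeatureSet",
    "ReactionGraph",
    "conditional_entropy",
    "greedy_entropy_select",
    "meta_learning_select",
    "kegg_select",
]


@dataclass
class FeatureSet:
    gene_ids: list[str]
    achieved_score: float
    method: str


def conditional_entropy(X_subset: np.ndarray, y: Sequence[int]) -> float:
    """Empirical conditional entropy H(y | x) in bits.

    Rows of ``X_subset`` with identical gene vectors form the conditioning
    groups: H(y|X) = sum_s P(x = x_s) H(y | x = x_s), with 0 log 0 = 0.
    """
    X = np.atleast_2d(np.asarray(X_subset))
    if X.shape[0] == 1 and np.asarray(y).size != 1:
        X = X.T  # a single gene passed as a flat vector
    yv = np.asarray(y, dtype=int)
    m = yv.size
    if m == 0 or X.shape[0] != m:
        raise ValueError("X_subset rows must align with y and be non-empty")
    _, inverse = np.unique(X, axis=0, return_inverse=True)
    n_groups = inverse.max() + 1
    group_sizes = np.bincount(inverse, minlength=n_groups)
    ones = np.bincount(inverse, weights=yv, minlength=n_groups)
    p1 = ones / group_sizes
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p1 > 0, p1 * np.log2(p1), 0.0)
              + np.where(p1 < 1, (1 - p1) * np.log2(1 - p1), 0.0))
    return float(np.sum(group_sizes / m * h))


def _beam_search(gene_ids, score_fn, k_max, beam_width, maximize, tol=1e-12):
    """Generic beam search over growing gene sets.

    ``score_fn(tuple_of_gene_indices) -> float``. Ties break on the sorted
    gene-ID tuple, so results are deterministic. Returns (best index tuple,
    best score). For minimization an exact-zero score stops early (no
    further gene can improve it).
    """
    n = len(gene_ids)
    k_max = min(k_max, n)
    sign = -1.0 if maximize else 1.0

    def key(item):
        idx, s = item
        return (sign * s, tuple(sorted(gene_ids[i] for i in idx)))

    scored = [((j,), score_fn((j,))) for j in range(n)]
    scored.sort(key=key)
    beam = scored[:beam_width]
    if not maximize and beam[0][1] <= tol:
        return beam[0]
    for _ in range(1, k_max):
        seen, candidates = set(), []
        for idx, _ in beam:
            present = set(idx)
            for j in range(n):
                if j in present:
                    continue
                new = frozenset(present | {j})
                if new in seen:
                    continue
                seen.add(new)
                tup = tuple(sorted(new))
                candidates.append((tup, score_fn(tup)))
        if not candidates:
            break
        candidates.sort(key=key)
        beam = candidates[:beam_width]
        if not maximize and beam[0][1] <= tol:
            break
    return beam[0]


def greedy_entropy_select(
    X: np.ndarray,
    y: Sequence[int],
    gene_ids: Sequence[str] | None = None,
    k_max: int = 5,
    beam_width: int = 5,
) -> FeatureSet:
    """Beam search for the gene set with minimal conditional entropy.

    Round r keeps the ``beam_width`` best r-gene sets and expands each with
    every remaining gene. Stops early once a zero-entropy set is found. With
    ``beam_width=1`` this degenerates to a purely greedy search that can
    miss jointly informative (e.g. XOR-coupled) gene pairs.
    """
    if k_max < 1 or beam_width < 1:
        raise ValueError("k_max and beam_width must be >= 1")
    X = np.asarray(X)
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(X.shape[1])]
    gene_ids = list(gene_ids)
    idx, score = _beam_search(
        gene_ids, lambda tup: conditional_entropy(X[:, tup], y),
        k_max, beam_width, maximize=False,
    )
    return FeatureSet(sorted(gene_ids[i] for i in idx), float(score), "entropy")


def meta_learning_select(
    X_train: np.ndarray,
    y_train: Sequence[int],
    train_ids: Sequence[str],
    tree: PhyloTree,
    gene_ids: Sequence[str] | None = None,
    k_max: int = 5,
    n_meta: int = 20,
    beam_width: int = 5,
    rng_seed: int | None = None,
    min_fraction: float = 0.10,
    max_fraction: float = 0.30,
) -> tuple[FeatureSet, DecisionTreeClassifier]:
    """Select genes that generalize across clades within the training set.

    The training strains are re-split ``n_meta`` times by the out-of-clade
    partitioning rules (meta-training / meta-test). A candidate gene set is
    scored by the mean meta-test accuracy of a decision tree fit on the
    meta-training strains (a depth-1 stump for single-gene sets). The beam
    search over sets is identical to the conditional-entropy variant. The
    returned classifier is a decision tree on the winning set, fit on the
    full training data.
    """
    X = np.asarray(X_train)
    y = np.asarray(y_train, dtype=int)
    train_ids = list(train_ids)
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(X.shape[1])]
    gene_ids = list(gene_ids)
    row = {s: i for i, s in enumerate(train_ids)}
    candidates = enumerate_clade_testsets(
        tree, min_fraction, max_fraction, restrict_to=train_ids
    )
    rng = np.random.default_rng(rng_seed)
    meta = []
    for _ in range(n_meta):
        part = out_of_clade_partition(
            tree, min_fraction, max_fraction,
            rng_seed=int(rng.integers(2**31)),
            restrict_to=train_ids, candidates=candidates,
        )
        meta.append((
            np.array([row[s] for s in part.train_ids]),
            np.array([row[s] for s in part.test_ids]),
        ))

    def meta_accuracy(tup: tuple[int, ...]) -> float:
        depth = 1 if len(tup) == 1 else None
        accs = []
        for tr, te in meta:
            clf = DecisionTreeClassifier(max_depth=depth, random_state=0)
            clf.fit(X[np.ix_(tr, tup)], y[tr])
            accs.append(float((clf.predict(X[np.ix_(te, tup)]) == y[te]).mean()))
        return float(np.mean(accs))

    idx, score_val = _beam_search(
        gene_ids, meta_accuracy, k_max, beam_width, maximize=True,
    )
    final = DecisionTreeClassifier(random_state=0)
    final.fit(X[:, idx], y)
    return (
        FeatureSet(sorted(gene_ids[i] for i in idx), float(score_val), "meta"),
        final,
    )


# ---------------------------------------------------------------------------
# reaction-graph selection


@dataclass
class Reaction:
    id: str
    substrate: str
    product: str
    genes: list[str] = field(default_factory=list)


@dataclass
class ReactionGraph:
    """Metabolite nodes, reaction edges, and pathway membership.

    Each reaction is directed substrate -> product as written; traversal may
    treat the graph as directed or undirected. ``pathways`` maps a pathway
    name to its member compounds and gene orthologs; ``destinations`` lists
    the central-metabolism compounds that path-based selection targets.
    """

    compounds: list[str]
    reactions: list[Reaction]
    pathways: dict[str, dict[str, list[str]]]
    destinations: list[str]

    def __post_init__(self) -> None:
        known = set(self.compounds)
        for r in self.reactions:
            if r.substrate not in known or r.product not in known:
                raise ValueError(f"reaction {r.id} references unknown compounds")

    @classmethod
    def from_json(cls, path) -> "ReactionGraph":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            compounds=list(raw["compounds"]),
            reactions=[Reaction(**r) for r in raw["reactions"]],
            pathways={k: {"compounds": list(v["compounds"]),
                          "genes": list(v["genes"])}
                      for k, v in raw["pathways"].items()},
            destinations=list(raw["destinations"]),
        )

    def to_json(self, path) -> None:
        raw = {
            "compounds": self.compounds,
            "reactions": [vars(r) for r in self.reactions],
            "pathways": self.pathways,
            "destinations": self.destinations,
        }
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=1)

    def edge_genes(self, u: str, v: str, directed: bool) -> set[str]:
        """Union of gene sets of all reactions realizing the hop u -> v."""
        genes: set[str] = set()
        for r in self.reactions:
            if (r.substrate, r.product) == (u, v):
                genes |= set(r.genes)
            elif not directed and (r.substrate, r.product) == (v, u):
                genes |= set(r.genes)
        return genes

    def to_networkx(self, directed: bool = True) -> nx.Graph:
        g = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(self.compounds)
        for r in self.reactions:
            g.add_edge(r.substrate, r.product)
        return g


def kegg_select(
    graph: ReactionGraph,
    carbon: str,
    level: str,
    top_k_paths: int = 3,
    directed: bool = True,
    destinations: Sequence[str] | None = None,
    max_path_len: int | None = None,
) -> set[str]:
    """Gene orthologs relevant to a carbon source, at one of three scopes.

    ``level="pathways"``: genes of every pathway containing the carbon.
    ``level="reactions"``: genes of reactions with the carbon as substrate
    or product. ``level="paths"``: enumerate loopless paths from the carbon
    to any destination compound, rank by reaction-step count (ties broken by
    the lexicographic compound sequence), keep the ``top_k_paths`` best, and
    union the gene sets of their reactions (fewer available paths than
    requested -> all are used).
    """
    if carbon not in graph.compounds:
        raise ValueError(f"compound {carbon!r} not in the reaction graph")
    if top_k_paths < 1:
        raise ValueError("top_k_paths must be >= 1")
    if level == "pathways":
        genes: set[str] = set()
        for pw in graph.pathways.values():
            if carbon in pw["compounds"]:
                genes |= set(pw["genes"])
        return genes
    if level == "reactions":
        genes = set()
        for r in graph.reactions:
            if carbon in (r.substrate, r.product):
                genes |= set(r.genes)
        return genes
    if level == "paths":
        dests = list(destinations if destinations is not None
                     else graph.destinations)
        g = graph.to_networkx(directed=directed)
        paths = set()
        for dest in dests:
            if dest == carbon or dest not in g:
                continue
            for p in nx.all_simple_paths(g, carbon, dest, cutoff=max_path_len):
                paths.add(tuple(p))
        if not paths:
            warnings.warn(
                f"no loopless path from {carbon!r} to any destination",
                stacklevel=2,
            )
            return set()
        ranked = sorted(paths, key=lambda p: (len(p) - 1, p))
        genes = set()
        for p in islice(ranked, top_k_paths):
            for u, v in zip(p[:-1], p[1:]):
                genes |= graph.edge_genes(u, v, directed)
        return genes
    raise ValueError(f"unknown selection level {level!r}")
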