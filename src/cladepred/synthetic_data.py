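"""Synthetic phylogenetically structured genotypes and boolean traits.

The generator stands in for a real strain collection: a random bifurcating
tree, gene presence/absence evolved along it as independent two-state
(gain/loss) Markov processes, and binary traits defined as random AND/OR
boolean expressions over a subset of "trait-defining" genes. A modularity
parameter constrains how evenly every node of the expression tree splits
its genes, emulating pathway-like trait architectures (e.g. (g1 AND g2) OR
(g3 AND g4) is more modular than ((g1 AND g2) OR g3) AND g4).

Defaults are chosen to resemble a 16S-scale phylogeny and pangenome-like
gene content: branch lengths ~ Exp(0.05) substitutions/site, and gain/loss
rates (0.67, 1.56) giving a stationary gene frequency of 0.30 and a
sibling-leaf state correlation near 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .dataio import GenotypeMatrix, PhyloTree

__all__ = [
    "LogicTrait",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_gene_content",
    "random_logic_trait",
    "evaluate_logic_trait",
    "generate_benchmark",
    "DEFAULT_BRANCH_SCALE",
    "DEFAULT_GAIN_RATE",
    "DEFAULT_LOSS_RATE",
]

DEFAULT_BRANCH_SCALE = 0.05
DEFAULT_GAIN_RATE = 0.67
DEFAULT_LOSS_RATE = 1.56


@dataclass
class LogicTrait:
    """Boolean AND/OR expression tree over gene IDs.

    ``expression`` is either a gene ID (leaf) or a triple
    ``(op, left, right)`` with ``op`` in {"AND", "OR"}. Every internal node
    satisfies min(|L|, |R|) / (|L| + |R|) >= modularity, where |.| counts
    leaf genes, so the parameter lives in [0, 0.5].
    """

    expression: object
    trait_gene_ids: list[str]
    modularity: float

    def __post_init__(self) -> None:
        genes = _leaf_genes(self.expression)
        if len(genes) != len(set(genes)):
            raise ValueError("trait genes must be distinct")
        if sorted(genes) != sorted(self.trait_gene_ids):
            raise ValueError("trait_gene_ids do not match the expression leaves")
        if not 0.0 <= self.modularity <= 0.5:
            raise ValueError("modularity must lie in [0, 0.5]")
        _check_modularity(self.expression, self.modularity)

    def __str__(self) -> str:
        return _format(self.expression)


def _leaf_genes(expr) -> list[str]:
    if isinstance(expr, str):
        return [expr]
    _, left, right = expr
    return _leaf_genes(left) + _leaf_genes(right)


def _check_modularity(expr, modularity: float) -> None:
    if isinstance(expr, str):
        return
    op, left, right = expr
    if op not in ("AND", "OR"):
        raise ValueError(f"unknown operator {op!r}")
    nl, nr = len(_leaf_genes(left)), len(_leaf_genes(right))
    if min(nl, nr) / (nl + nr) < modularity - 1e-12:
        raise ValueError(
            f"split {nl}|{nr} violates modularity {modularity}"
        )
    _check_modularity(left, modularity)
    _check_modularity(right, modularity)


def _format(expr) -> str:
    if isinstance(expr, str):
        return expr
    op, left, right = expr
    return f"({_format(left)} {op} {_format(right)})"


@dataclass
class SyntheticDataset:
    """One benchmark cell: genotypes, tree, and balanced logic traits."""

    genotypes: GenotypeMatrix
    tree: PhyloTree
    traits: list[tuple[LogicTrait, np.ndarray]]
    params: dict = field(default_factory=dict)
    feasible: bool = True


def simulate_tree(n_leaves: int, branch_scale: float = DEFAULT_BRANCH_SCALE,
                  rng_seed: int | None = None) -> PhyloTree:
    """Random bifurcating tree by sequential random leaf attachment.

    Each new leaf splits the external branch of a uniformly chosen existing
    leaf; all branch lengths are then drawn i.i.d. Exp(branch_scale).
    Leaves are labelled ``s0000, s0001, ...``.
    """
    if n_leaves < 2:
        raise ValueError("a tree needs at least 2 leaves")
    rng = np.random.default_rng(rng_seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    width = max(4, len(str(n_leaves)))

    def new_leaf(i: int) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label=f"s{i:0{width}d}")
        return node

    leaves = [new_leaf(0), new_leaf(1)]
    tree.seed_node.add_child(leaves[0])
    tree.seed_node.add_child(leaves[1])
    for i in range(2, n_leaves):
        target = leaves[rng.integers(len(leaves))]
        parent = target.parent_node
        joint = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(joint)
        joint.add_child(target)
        fresh = new_leaf(i)
        joint.add_child(fresh)
        leaves.append(fresh)
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node.edge.length = float(rng.exponential(branch_scale))
    return PhyloTree(tree)


def _transition(state: np.ndarray, t: float, gain: float, loss: float,
                rng: np.random.Generator) -> np.ndarray:
    """Evolve binary gene states for time t under the gain/loss chain."""
    rate = gain + loss
    pi1 = gain / rate
    decay = np.exp(-rate * t)
    p1 = np.where(state == 1, pi1 + (1 - pi1) * decay, pi1 * (1 - decay))
    return (rng.random(state.shape) < p1).astype(np.int8)


def simulate_gene_content(tree: PhyloTree, n_genes: int,
                          gain_rate: float = DEFAULT_GAIN_RATE,
                          loss_rate: float = DEFAULT_LOSS_RATE,
                          rng_seed: int | None = None) -> GenotypeMatrix:
    """Evolve gene presence/absence along the tree.

    Each gene is an independent two-state Markov chain with gain rate
    (0 -> 1) and loss rate (1 -> 0); the root draws from the stationary
    distribution pi_1 = gain / (gain + loss).
    """
    if gain_rate <= 0 or loss_rate <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(rng_seed)
    pi1 = gain_rate / (gain_rate + loss_rate)
    dt = tree.dendropy_tree
    states: dict[int, np.ndarray] = {
        id(dt.seed_node): (rng.random(n_genes) < pi1).astype(np.int8)
    }
    rows, labels = [], []
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        state = _transition(parent_state, node.edge.length or 0.0,
                            gain_rate, loss_rate, rng)
        states[id(node)] = state
        if node.is_leaf():
            labels.append(node.taxon.label)
            rows.append(state)
    gene_ids = [f"g{j:05d}" for j in range(n_genes)]
    order = np.argsort(labels)
    return GenotypeMatrix(
        [labels[i] for i in order], gene_ids, np.array(rows)[order]
    )


def _split_feasible(m: int, modularity: float, cache: dict) -> bool:
    if m == 1:
        return True
    if m in cache:
        return cache[m]
    ok = any(
        min(l, m - l) / m >= modularity - 1e-12
        and _split_feasible(l, modularity, cache)
        and _split_feasible(m - l, modularity, cache)
        for l in range(1, m // 2 + 1)
    )
    cache[m] = ok
    return ok


def _grow(genes: list[str], modularity: float, rng: np.random.Generator,
          cache: dict):
    m = len(genes)
    if m == 1:
        return genes[0]
    valid = [l for l in range(1, m)
             if min(l, m - l) / m >= modularity - 1e-12
             and _split_feasible(l, modularity, cache)
             and _split_feasible(m - l, modularity, cache)]
    l = int(valid[rng.integers(len(valid))])
    op = "AND" if rng.random() < 0.5 else "OR"
    return (op, _grow(genes[:l], modularity, rng, cache),
            _grow(genes[l:], modularity, rng, cache))


def random_logic_trait(gene_pool: Sequence[str], n_trait_genes: int,
                       modularity: float = 0.0,
                       rng_seed: int | None = None) -> LogicTrait:
    """Random AND/OR expression over genes sampled from ``gene_pool``."""
    if n_trait_genes < 1:
        raise ValueError("n_trait_genes must be >= 1")
    if not 0.0 <= modularity <= 0.5:
        raise ValueError("modularity must lie in [0, 0.5]")
    pool = list(gene_pool)
    if n_trait_genes > len(pool):
        raise ValueError("gene pool smaller than n_trait_genes")
    cache: dict = {}
    if not _split_feasible(n_trait_genes, modularity, cache):
        raise ValueError(
            f"modularity {modularity} is unreachable for "
            f"{n_trait_genes} trait genes (no valid split exists)"
        )
    rng = np.random.default_rng(rng_seed)
    genes = [pool[i] for i in
             rng.choice(len(pool), size=n_trait_genes, replace=False)]
    expr = _grow(genes, modularity, rng, cache)
    return LogicTrait(expr, sorted(genes), modularity)


def evaluate_logic_trait(trait: LogicTrait,
                         genotypes: GenotypeMatrix) -> np.ndarray:
    """Evaluate the boolean expression per strain (vectorized)."""
    col = {g: j for j, g in enumerate(genotypes.gene_ids)}
    missing = [g for g in trait.trait_gene_ids if g not in col]
    if missing:
        raise ValueError(f"trait genes absent from genotype matrix: {missing}")

    def ev(expr) -> np.ndarray:
        if isinstance(expr, str):
            return genotypes.values[:, col[expr]].astype(bool)
        op, left, right = expr
        return ev(left) & ev(right) if op == "AND" else ev(left) | ev(right)

    return ev(trait.expression).astype(np.int8)


def generate_benchmark(
    tree: PhyloTree,
    genotypes: GenotypeMatrix,
    n_samples_grid: Sequence[int],
    n_genes_grid: Sequence[int],
    n_trait_genes_grid: Sequence[int],
    modularity: float = 0.0,
    n_traits: int = 50,
    min_class_fraction: float = 0.10,
    rng_seed: int | None = None,
    max_retries: int = 1000,
) -> list[SyntheticDataset]:
    """Benchmark grid of subsampled datasets with balanced logic traits.

    For every (n_samples, n_genes, n_trait_genes) cell: subsample strains
    and genes without replacement, then rejection-sample logic traits (trait
    genes drawn from the retained genes) until ``n_traits`` traits have at
    least ``min_class_fraction`` of each class, with at most ``max_retries``
    draws per trait. Cells whose retry budget is exhausted are returned with
    ``feasible=False`` and however many traits were found.
    """
    if not (n_samples_grid and n_genes_grid and n_trait_genes_grid):
        raise ValueError("all grids must be non-empty")
    rng = np.random.default_rng(rng_seed)
    out = []
    for n_samples in n_samples_grid:
        for n_genes in n_genes_grid:
            for n_trait_genes in n_trait_genes_grid:
                if n_samples > genotypes.n_strains or n_genes > genotypes.n_genes:
                    raise ValueError("grid cell exceeds the source dataset size")
                strains = sorted(
                    genotypes.strain_ids[i] for i in
                    rng.choice(genotypes.n_strains, n_samples, replace=False))
                genes = sorted(
                    genotypes.gene_ids[j] for j in
                    rng.choice(genotypes.n_genes, n_genes, replace=False))
                sub = genotypes.subset(strains, genes)
                subtree = tree.restrict(strains)
                traits, feasible = [], True
                for _ in range(n_traits):
                    found = None
                    for _ in range(max_retries):
                        lt = random_logic_trait(
                            genes, n_trait_genes, modularity,
                            rng_seed=int(rng.integers(2**31)))
                        vec = evaluate_logic_trait(lt, sub)
                        frac = vec.mean()
                        if min_class_fraction <= frac <= 1 - min_class_fraction:
                            found = (lt, vec)
                            break
                    if found is None:
                        feasible = False
                        break
                    traits.append(found)
                out.append(SyntheticDataset(
                    genotypes=sub, tree=subtree, traits=traits,
                    params={
                        "n_samples": n_samples, "n_genes": n_genes,
                        "n_trait_genes": n_trait_genes,
                        "modularity": modularity, "n_traits": n_traits,
                        "min_class_fraction": min_class_fraction,
                        "seed": rng_seed,
                    },
                    feasible=feasible,
                ))
    return out
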