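"""Prepackaged simulation experiments.

``scaled_sample_size_study`` reproduces, at desk scale, the synthetic
sample-size experiment: simulate a large strain collection (tree + gene
content), subsample it to several sample sizes, define random boolean
traits over a few trait-defining genes, and benchmark the random forest
under random and out-of-clade partitioning against both null models. The
defaults (10 traits, 20 partitions, 300 genes, 3 trait genes, sample sizes
100 and 1000) are chosen so a full run completes in minutes on one core
while preserving the qualitative behaviour of the full-size design: the
out-of-clade accuracy of the forest should rise with sample size, and at
the larger size the forest should beat both nulls and concentrate its
importance on the trait-defining genes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .dataio import TraitTable
from .pipeline import BenchmarkConfig, run_benchmark
from .synthetic_data import generate_benchmark, simulate_gene_content, simulate_tree

__all__ = ["scaled_sample_size_study"]


def scaled_sample_size_study(
    seed: int,
    n_samples_grid: Sequence[int] = (100, 1000),
    n_genes: int = 300,
    n_trait_genes: int = 3,
    modularity: float = 0.0,
    n_traits: int = 10,
    n_partitions: int = 20,
    regimes: tuple[str, ...] = ("random", "out_of_clade"),
) -> dict[int, dict]:
    """Run the scaled synthetic sample-size benchmark.

    Returns a mapping ``n_samples -> {"summary": DataFrame, "detail": dict,
    "trait_genes": {trait_id: [gene ids]}}`` where the summary/detail are
    the standard benchmark outputs for the random forest on that subsample.
    """
    rng = np.random.default_rng(seed)
    n_master = max(n_samples_grid)
    tree = simulate_tree(n_master, rng_seed=int(rng.integers(2**31)))
    genotypes = simulate_gene_content(tree, n_genes,
                                      rng_seed=int(rng.integers(2**31)))
    datasets = generate_benchmark(
        tree, genotypes, list(n_samples_grid), [n_genes], [n_trait_genes],
        modularity=modularity, n_traits=n_traits,
        rng_seed=int(rng.integers(2**31)))
    out: dict[int, dict] = {}
    for ds in datasets:
        n = ds.params["n_samples"]
        trait_ids = [f"trait{k:02d}" for k in range(len(ds.traits))]
        table = TraitTable(
            ds.genotypes.strain_ids, trait_ids,
            np.column_stack([vec for _, vec in ds.traits]).astype(float))
        config = BenchmarkConfig(
            models=("random_forest",), regimes=regimes,
            n_partitions=n_partitions, seed=int(rng.integers(2**31)))
        summary, detail = run_benchmark(
            config, genotypes=ds.genotypes, traits=table, tree=ds.tree)
        out[n] = {
            "summary": summary,
            "detail": detail,
            "trait_genes": {tid: lt.trait_gene_ids
                            for tid, (lt, _) in zip(trait_ids, ds.traits)},
        }
    return out
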