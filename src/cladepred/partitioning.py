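"""Train/test partitioning: random hold-out and out-of-clade hold-out.

The out-of-clade regime holds out one entire clade, or the union of two
leaf-disjoint clades, whose combined size falls inside a target fraction
window of the usable strains (default 10-30%). Predicting for a held-out
clade forces the model to extrapolate beyond the phylogenetic neighbourhood
of the training set, which is where purely phylogeny-driven classifiers
break down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import PhyloTree

__all__ = [
    "Partition",
    "random_partition",
    "enumerate_clade_testsets",
    "out_of_clade_partition",
]


@dataclass
class Partition:
    """One train/test split of the usable strains."""

    train_ids: list[str]
    test_ids: list[str]
    regime: str  # "random" | "out_of_clade"
    seed: int | None = None
    clade_leaf_sets: tuple[frozenset, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.regime not in ("random", "out_of_clade"):
            raise ValueError(f"unknown regime {self.regime!r}")
        train, test = set(self.train_ids), set(self.test_ids)
        if not test:
            raise ValueError("test set must be non-empty")
        if train & test:
            raise ValueError("train and test sets overlap")
        if self.regime == "out_of_clade":
            if not 1 <= len(self.clade_leaf_sets) <= 2:
                raise ValueError("out-of-clade test set must be 1 or 2 clades")
            if set().union(*self.clade_leaf_sets) != test:
                raise ValueError("clade leaves do not cover the test set")

    @property
    def all_ids(self) -> list[str]:
        return self.train_ids + self.test_ids


def random_partition(strain_ids: Sequence[str], test_fraction: float = 0.20,
                     rng_seed: int | None = None) -> Partition:
    """Hold out ``round(test_fraction * n)`` strains uniformly at random."""
    strain_ids = list(strain_ids)
    n = len(strain_ids)
    if n < 2:
        raise ValueError("need at least 2 strains to partition")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = max(1, round(test_fraction * n))
    if n_test >= n:
        n_test = n - 1
    rng = np.random.default_rng(rng_seed)
    test_idx = rng.choice(n, size=n_test, replace=False)
    test = {strain_ids[i] for i in test_idx}
    return Partition(
        train_ids=[s for s in strain_ids if s not in test],
        test_ids=[s for s in strain_ids if s in test],
        regime="random",
        seed=rng_seed,
    )


def enumerate_clade_testsets(
    tree: PhyloTree,
    min_fraction: float = 0.10,
    max_fraction: float = 0.30,
    restrict_to: Sequence[str] | None = None,
) -> list[tuple[frozenset, ...]]:
    """All candidate out-of-clade test sets on ``tree``.

    A candidate is one clade, or an unordered pair of leaf-disjoint clades
    that are each individually inside the size window, whose (combined) leaf
    count lies in ``[ceil(min_fraction*n), floor(max_fraction*n)]`` where
    ``n`` counts usable leaves. ``restrict_to`` prunes the tree to the usable
    strains (e.g. strains with a non-missing trait value) before any size
    accounting, so the window applies to usable samples.
    """
    if not 0 < min_fraction < max_fraction < 1:
        raise ValueError("need 0 < min_fraction < max_fraction < 1")
    if restrict_to is not None:
        tree = tree.restrict(restrict_to)
    n = tree.n_leaves
    if n < 4:
        raise ValueError("tree must have at least 4 usable leaves")
    lo = math.ceil(min_fraction * n)
    hi = math.floor(max_fraction * n)
    if lo > hi:
        raise ValueError(
            f"empty size window for n={n}: [{min_fraction}, {max_fraction}] "
            f"admits no integer leaf count"
        )
    clades = tree.clade_leaf_sets(include_leaves=(lo <= 1))
    # deduplicate identical leaf sets (can arise after pruning unifurcations)
    singles = sorted({c for c in clades if lo <= len(c) <= hi},
                     key=lambda c: tuple(sorted(c)))
    candidates: list[tuple[frozenset, ...]] = [(c,) for c in singles]
    for i in range(len(singles)):
        for j in range(i + 1, len(singles)):
            a, b = singles[i], singles[j]
            if a & b:
                continue  # nested or overlapping clades double-count leaves
            if lo <= len(a) + len(b) <= hi:
                candidates.append((a, b))
    if not candidates:
        raise ValueError(
            f"no clade test set with {lo}-{hi} of {n} leaves exists; "
            "the tree is too unbalanced for this size window"
        )
    return candidates


def out_of_clade_partition(
    tree: PhyloTree,
    min_fraction: float = 0.10,
    max_fraction: float = 0.30,
    rng_seed: int | None = None,
    restrict_to: Sequence[str] | None = None,
    candidates: list[tuple[frozenset, ...]] | None = None,
) -> Partition:
    """Hold out one candidate clade test set chosen uniformly.

    ``candidates`` may be passed to reuse one enumeration across many
    partitions of the same tree.
    """
    if candidates is None:
        candidates = enumerate_clade_testsets(
            tree, min_fraction, max_fraction, restrict_to=restrict_to
        )
    usable = sorted(restrict_to) if restrict_to is not None else sorted(tree.leaf_labels)
    rng = np.random.default_rng(rng_seed)
    chosen = candidates[rng.integers(len(candidates))]
    test = set().union(*chosen)
    return Partition(
        train_ids=[s for s in usable if s not in test],
        test_ids=[s for s in usable if s in test],
        regime="out_of_clade",
        seed=rng_seed,
        clade_leaf_sets=tuple(chosen),
    )
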