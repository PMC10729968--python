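"""Input/output and core containers for trait-prediction benchmarks.

The analysis works on three kinds of data that must stay aligned by strain
identifier:

* a binary strain x gene presence/absence matrix (:class:`GenotypeMatrix`),
* a binary strain x trait growth table that may contain missing entries
  (:class:`TraitTable`),
* a rooted phylogeny with branch lengths (:class:`PhyloTree`), from which
  patristic distances are derived.

All tabular files are plain TSV (UTF-8, ``NA`` for missing values); trees are
Newick; marker-gene alignments are aligned FASTA.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.spatial.distance import squareform

MISSING_TOKEN = "NA"

__all__ = [
    "GenotypeMatrix",
    "TraitTable",
    "PhyloTree",
    "DistanceMatrix",
    "load_genotype_matrix",
    "load_trait_table",
    "load_tree",
    "load_alignment",
    "binarize_growth",
    "filter_traits",
    "distance_matrix",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise ValueError(f"duplicate {what}: {sorted(dups)}")
    return ids


@dataclass
class GenotypeMatrix:
    """Binary strains x genes presence/absence matrix (no missing entries)."""

    strain_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.strain_ids = _check_unique(self.strain_ids, "strain IDs")
        self.gene_ids = _check_unique(self.gene_ids, "gene IDs")
        arr = np.asarray(self.values)
        if arr.shape != (len(self.strain_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {arr.shape} does not match "
                f"{len(self.strain_ids)} strains x {len(self.gene_ids)} genes"
            )
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary value {arr[r, c]!r} at strain "
                f"{self.strain_ids[r]!r}, gene {self.gene_ids[c]!r}"
            )
        self.values = arr.astype(np.int8)

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strain_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def subset(self, strain_ids: Sequence[str] | None = None,
               gene_ids: Sequence[str] | None = None) -> "GenotypeMatrix":
        frame = self.to_frame()
        if strain_ids is not None:
            frame = frame.loc[list(strain_ids)]
        if gene_ids is not None:
            frame = frame[list(gene_ids)]
        return GenotypeMatrix.from_frame(frame)

    def rows(self, strain_ids: Sequence[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.strain_ids)}
        return self.values[[idx[s] for s in strain_ids]]

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="strain")


@dataclass
class TraitTable:
    """Binary strains x traits table; missing entries stored as NaN."""

    strain_ids: list[str]
    trait_ids: list[str]
    values: np.ndarray  # float array, NaN = missing

    def __post_init__(self) -> None:
        self.strain_ids = _check_unique(self.strain_ids, "strain IDs")
        self.trait_ids = _check_unique(self.trait_ids, "trait IDs")
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(self.strain_ids), len(self.trait_ids)):
            raise ValueError("trait table shape does not match its IDs")
        ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0))
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ValueError(
                f"non-binary trait value {arr[r, c]!r} at strain "
                f"{self.strain_ids[r]!r}, trait {self.trait_ids[c]!r}"
            )
        self.values = arr

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strain_ids, columns=self.trait_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TraitTable":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def trait(self, trait_id: str) -> pd.Series:
        """One trait as a Series indexed by strain, missing entries dropped."""
        j = self.trait_ids.index(trait_id)
        s = pd.Series(self.values[:, j], index=self.strain_ids, name=trait_id)
        return s.dropna().astype(int)

    def save(self, path) -> None:
        frame = self.to_frame()
        out = frame.map(lambda v: MISSING_TOKEN if np.isnan(v) else str(int(v)))
        out.to_csv(path, sep="\t", index_label="strain")


class PhyloTree:
    """Rooted phylogeny with finite, non-negative branch lengths.

    Thin wrapper over a :class:`dendropy.Tree` that enforces unique leaf
    labels and provides the traversals the benchmark needs (clade leaf sets,
    patristic distances, restriction to a strain subset).
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("every leaf must be labelled")
            labels.append(leaf.taxon.label)
        self.leaf_labels = _check_unique(labels, "leaf labels")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            ln = edge.length
            if ln is None:
                edge.length = 0.0
            elif not np.isfinite(ln) or ln < 0:
                raise ValueError(f"invalid branch length {ln!r}")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    def clade_leaf_sets(self, include_leaves: bool = True) -> list[frozenset[str]]:
        """Leaf-label set of every clade (subtree) below the root."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.is_leaf():
                if include_leaves:
                    out.append(frozenset([node.taxon.label]))
            else:
                out.append(frozenset(l.taxon.label for l in node.leaf_iter()))
        return out

    def restrict(self, labels: Iterable[str]) -> "PhyloTree":
        """Subtree induced by ``labels`` (suppresses unifurcations)."""
        keep = set(labels)
        missing = keep - set(self.leaf_labels)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        tree = self._tree.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True
        )
        return PhyloTree(tree)

    def patristic_matrix(self) -> "DistanceMatrix":
        """All pairwise leaf-to-leaf path-length distances."""
        labels = sorted(self.leaf_labels)
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))
        # depth of each node from the root, then d(a,b) = da + db - 2*d(mrca)
        depth: dict[int, float] = {id(self._tree.seed_node): 0.0}
        below: dict[int, np.ndarray] = {}
        for node in self._tree.preorder_node_iter():
            if node is not self._tree.seed_node:
                depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
        leaf_depth = np.zeros(n)
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = index[node.taxon.label]
                below[id(node)] = np.array([i])
                leaf_depth[i] = depth[id(node)]
            else:
                children = [below[id(c)] for c in node.child_nodes()]
                for a in range(len(children)):
                    for b in range(a + 1, len(children)):
                        ia, ib = children[a], children[b]
                        d = (leaf_depth[ia][:, None] + leaf_depth[ib][None, :]
                             - 2.0 * depth[id(node)])
                        dist[np.ix_(ia, ib)] = d
                        dist[np.ix_(ib, ia)] = d.T
                below[id(node)] = np.concatenate(children)
        return DistanceMatrix(labels, dist, metric="patristic")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between strains, tagged by metric."""

    strain_ids: list[str]
    values: np.ndarray
    metric: str = "patristic"

    def __post_init__(self) -> None:
        self.strain_ids = _check_unique(self.strain_ids, "strain IDs")
        arr = np.asarray(self.values, dtype=float)
        n = len(self.strain_ids)
        if arr.shape != (n, n):
            raise ValueError("distance matrix must be square over strain_ids")
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (arr < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = arr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strain_ids, columns=self.strain_ids)

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = {s: i for i, s in enumerate(self.strain_ids)}
        sel = [idx[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(sel, sel)], self.metric)

    def between(self, row_ids: Sequence[str], col_ids: Sequence[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.strain_ids)}
        return self.values[np.ix_([idx[s] for s in row_ids], [idx[s] for s in col_ids])]

    def condensed_pairs(self):
        """(i, j, d) for all unordered pairs, i < j in ``strain_ids`` order."""
        iu, ju = np.triu_indices(len(self.strain_ids), k=1)
        return iu, ju, self.values[iu, ju]


# ---------------------------------------------------------------------------
# loaders


def load_genotype_matrix(path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        values = frame.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in genotype matrix: {exc}") from exc
    return GenotypeMatrix(list(frame.index.astype(str)), list(frame.columns), values)


def load_trait_table(path) -> TraitTable:
    frame = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        na_values=[MISSING_TOKEN], keep_default_na=False,
    )
    return TraitTable(
        list(frame.index.astype(str)), list(frame.columns),
        frame.astype(float).to_numpy(),
    )


def load_tree(path) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def load_alignment(path) -> tuple[list[str], np.ndarray]:
    """Aligned FASTA -> (sequence IDs, character matrix).

    Gap characters are kept as ordinary symbols: a gap matches a gap and
    mismatches everything else.
    """
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    mat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _check_unique(ids, "sequence IDs"), mat.reshape(len(ids), -1)


# ---------------------------------------------------------------------------
# data-cleaning operations


def binarize_growth(od_table: pd.DataFrame, threshold: float = 0.2) -> TraitTable:
    """Binarize raw optical-density readings into a growth/no-growth table.

    ``od_table`` has columns ``strain``, ``condition``, and two replicate
    columns ``od1``/``od2``. A strain grows on a condition when both
    replicates reach ``threshold``; replicates that disagree after
    binarization are treated as missing (the entry is removed).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    required = {"strain", "condition", "od1", "od2"}
    if not required.issubset(od_table.columns):
        raise ValueError(f"od_table needs columns {sorted(required)}")
    od = od_table[["od1", "od2"]].to_numpy(dtype=float)
    if (od < 0).any():
        raise ValueError("negative OD reading")
    b = od >= threshold
    call = np.where(b[:, 0] == b[:, 1], b[:, 0].astype(float), np.nan)
    table = od_table[["strain", "condition"]].copy()
    table["call"] = call
    wide = table.pivot(index="strain", columns="condition", values="call")
    return TraitTable.from_frame(wide)


def filter_traits(traits: TraitTable, min_per_class: int = 10) -> TraitTable:
    """Drop traits with fewer than ``min_per_class`` non-missing 0s or 1s."""
    if min_per_class < 1:
        raise ValueError("min_per_class must be >= 1")
    keep = []
    for j, t in enumerate(traits.trait_ids):
        col = traits.values[:, j]
        ones = np.nansum(col == 1)
        zeros = np.nansum(col == 0)
        if ones >= min_per_class and zeros >= min_per_class:
            keep.append(t)
    frame = traits.to_frame()[keep]
    return TraitTable.from_frame(frame)


def distance_matrix(data, metric: str) -> DistanceMatrix:
    """Pairwise strain distances under one of the supported metrics.

    metric="patristic"
        ``data`` is a :class:`PhyloTree`; distance = summed branch lengths
        on the path between two leaves.
    metric="hamming"
        ``data`` is ``(ids, char_matrix)`` from :func:`load_alignment`;
        distance = raw count of mismatching alignment columns.
    metric="l1"
        ``data`` is a :class:`GenotypeMatrix`; distance = number of genes
        whose presence/absence differs.
    """
    if metric == "patristic":
        if not isinstance(data, PhyloTree):
            raise TypeError("patristic distances require a PhyloTree")
        return data.patristic_matrix()
    if metric == "hamming":
        ids, mat = data
        from scipy.spatial.distance import pdist
        d = pdist(mat, metric="hamming") * mat.shape[1]
        return DistanceMatrix(list(ids), squareform(np.round(d)), metric="hamming")
    if metric == "l1":
        if not isinstance(data, GenotypeMatrix):
            raise TypeError("l1 distances require a GenotypeMatrix")
        from scipy.spatial.distance import pdist
        d = pdist(data.values.astype(float), metric="cityblock")
        return DistanceMatrix(list(data.strain_ids), squareform(d), metric="l1")
    raise ValueError(f"unknown metric {metric!r}")
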