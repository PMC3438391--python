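"""Nei gene-diversity statistics: hierarchical FST partition, genetic
distance, and the carrier-frequency clustering of populations and loci.

The hierarchical partition decomposes total gene diversity HT into a
within-population component HS, a between-population-within-region component
(HR - HS) and a between-region component (HT - HR), reported as proportions
of HT.  By default populations and regions enter all means unweighted; with
``weighted=True`` populations are weighted by sample size (equivalent to
pooling allele counts), and ``unbiased=True`` applies Nei's small-sample
correction 2n/(2n-1) to each within-population diversity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "AlleleFrequencyMatrix", "FstPartition", "ClusterResult",
    "gene_diversity", "hierarchical_partition", "nei_standard_distance",
    "cluster_frequencies",
]

#: Sentinel for an infinite Nei distance (zero normalized identity).
INFINITE_DISTANCE = math.inf


@dataclass(frozen=True)
class AlleleFrequencyMatrix:
    """Per-population allele frequencies of one locus, with region labels.

    ``freqs`` is a population x allele DataFrame whose rows sum to 1;
    ``regions`` and ``n`` are aligned per-population Series.
    """

    freqs: pd.DataFrame
    regions: pd.Series
    n: pd.Series

    def __post_init__(self) -> None:
        rowsum = self.freqs.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            bad = rowsum[~np.isclose(rowsum, 1.0, atol=1e-9)]
            raise ValueError(f"rows do not sum to 1: {list(bad.index)}")
        for s in (self.regions, self.n):
            if not s.index.equals(self.freqs.index):
                raise ValueError("regions/n index must match freqs index")


@dataclass(frozen=True)
class FstPartition:
    """Proportions of total gene diversity at the three hierarchy levels."""

    within_populations: float
    between_populations: float
    between_regions: float

    def __post_init__(self) -> None:
        total = (self.within_populations + self.between_populations
                 + self.between_regions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"components sum to {total}, not 1")
        if min(self.within_populations, self.between_populations,
               self.between_regions) < 0:
            raise ValueError("components must be >= 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.within_populations, self.between_populations,
                self.between_regions)


def gene_diversity(freqs: Sequence[float]) -> float:
    """Nei gene diversity (expected heterozygosity) ``1 - sum(p^2)``."""
    p = np.asarray(freqs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return float(1.0 - (p ** 2).sum())


def hierarchical_partition(
    m: AlleleFrequencyMatrix,
    weighted: bool = False,
    unbiased: bool = False,
) -> FstPartition:
    """Partition total gene diversity within/between populations and regions.

    HS is the mean within-population diversity; HR averages, over regions,
    the diversity of each region's mean frequency vector; HT is the diversity
    of the global mean vector.  Returned proportions are
    ``(HS/HT, (HR-HS)/HT, (HT-HR)/HT)``.  Raw negative between components
    (possible with unweighted means and sampling noise) are clamped to zero
    with a warning and the triple renormalized.
    """
    F = m.freqs.to_numpy(dtype=float)
    if F.shape[0] < 2:
        raise ValueError("need >= 2 populations")
    npop = F.shape[0]
    w = m.n.to_numpy(dtype=float) if weighted else np.ones(npop)

    h = 1.0 - (F ** 2).sum(axis=1)
    if unbiased:
        two_n = 2.0 * m.n.to_numpy(dtype=float)
        h = h * two_n / (two_n - 1.0)
    HS = float(np.average(h, weights=w))

    regions = m.regions.to_numpy()
    region_names = sorted(set(regions))
    region_means, region_weights = [], []
    for r in region_names:
        idx = regions == r
        region_means.append(np.average(F[idx], axis=0, weights=w[idx]))
        region_weights.append(w[idx].sum())
    region_means = np.asarray(region_means)
    region_weights = np.asarray(region_weights) if weighted else None
    HR = float(np.average(
        1.0 - (region_means ** 2).sum(axis=1), weights=region_weights))
    global_mean = np.average(region_means, axis=0, weights=region_weights)
    HT = float(1.0 - (global_mean ** 2).sum())

    if HT <= 0.0:
        raise ValueError("monomorphic data: HT = 0, partition undefined")

    comps = np.array([HS / HT, (HR - HS) / HT, (HT - HR) / HT])
    if (comps < 0).any():
        warnings.warn(
            f"negative raw partition component(s) {comps.tolist()} clamped to 0",
            RuntimeWarning, stacklevel=2)
        comps = np.clip(comps, 0.0, None)
        comps = comps / comps.sum()
    return FstPartition(*map(float, comps))


def nei_standard_distance(
    p1: Sequence[float] | Sequence[Sequence[float]],
    p2: Sequence[float] | Sequence[Sequence[float]],
) -> float:
    """Nei (1972) standard genetic distance between two populations.

    ``p1`` and ``p2`` are allele-frequency vectors of one locus, or lists of
    such vectors over several loci (identities are summed across loci before
    the log).  Returns ``-ln( J12 / sqrt(J1 * J2) )``; an identity of zero
    yields the :data:`INFINITE_DISTANCE` sentinel.
    """
    a1 = [np.asarray(v, dtype=float) for v in _as_loci(p1)]
    a2 = [np.asarray(v, dtype=float) for v in _as_loci(p2)]
    if len(a1) != len(a2) or any(x.shape != y.shape for x, y in zip(a1, a2)):
        raise ValueError("mismatched allele sets")
    j12 = sum(float(x @ y) for x, y in zip(a1, a2))
    j1 = sum(float(x @ x) for x in a1)
    j2 = sum(float(y @ y) for y in a2)
    identity = j12 / math.sqrt(j1 * j2)
    if identity <= 0.0:
        return INFINITE_DISTANCE
    return -math.log(min(identity, 1.0))


def _as_loci(p):
    arr = np.asarray(p, dtype=float)
    return [arr] if arr.ndim == 1 else list(arr)


@dataclass(frozen=True)
class ClusterResult:
    """Row/column dendrograms of a frequency matrix.

    ``row_order``/``column_order`` are the dendrogram leaf orders;
    ``row_linkage``/``column_linkage`` the scipy linkage matrices.
    """

    row_labels: tuple[str, ...]
    column_labels: tuple[str, ...]
    row_order: tuple[str, ...]
    column_order: tuple[str, ...]
    row_linkage: np.ndarray
    column_linkage: np.ndarray

    def row_subtrees(self) -> list[frozenset[str]]:
        """Leaf-label sets of every internal node of the row dendrogram."""
        return _subtrees(self.row_linkage, self.row_labels)

    def row_newick(self) -> str:
        return _to_newick(self.row_linkage, self.row_labels)

    def column_newick(self) -> str:
        return _to_newick(self.column_linkage, self.column_labels)


def _subtrees(Z: np.ndarray, labels: Sequence[str]) -> list[frozenset[str]]:
    tree = hierarchy.to_tree(Z)
    out: list[frozenset[str]] = []

    def walk(node):
        if node.is_leaf():
            return frozenset({labels[node.id]})
        leaves = walk(node.left) | walk(node.right)
        out.append(leaves)
        return leaves

    walk(tree)
    return out


def _to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def fmt(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        inner = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
        return f"({inner}):{length:.6g}"

    inner = ",".join(fmt(c, tree.dist) for c in (tree.left, tree.right))
    return f"({inner});"


def cluster_frequencies(table: pd.DataFrame) -> ClusterResult:
    """Agglomerative clustering of a frequency table's rows and columns.

    Euclidean dissimilarity with complete linkage on both axes (the defaults
    of the classic clustered-heatmap routine); scipy's deterministic
    tie-breaking keeps the result stable for a given input order.  A constant
    matrix yields degenerate zero-height trees.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    X = table.to_numpy(dtype=float)
    row_Z = hierarchy.linkage(pdist(X), method="complete")
    col_Z = hierarchy.linkage(pdist(X.T), method="complete")
    row_labels = tuple(map(str, table.index))
    col_labels = tuple(map(str, table.columns))
    return ClusterResult(
        row_labels=row_labels,
        column_labels=col_labels,
        row_order=tuple(row_labels[i] for i in hierarchy.leaves_list(row_Z)),
        column_order=tuple(col_labels[i] for i in hierarchy.leaves_list(col_Z)),
        row_linkage=row_Z,
        column_linkage=col_Z,
    )
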