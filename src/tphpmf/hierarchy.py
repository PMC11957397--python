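"""Three-level phylogenetic hierarchy over taxa.

Taxa are organized by complete-linkage agglomerative clustering of a
phylogenetic (patristic) distance matrix.  Cutting the dendrogram at three
increasing heights yields nested partitions labelled "S" (finest), "G" and
"F" (coarsest) — species-, genus- and family-like groupings.  The matrix
actually imputed lives below "S" at the level of individual taxa, so the
imputation engine sees four layers: taxa, S, G, F.

Cluster ids are deterministic: within a level, clusters are numbered by
their smallest member taxon index.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import skbio
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .preprocessing import DEFAULT_LIBRARY_SIZE, DEFAULT_OFFSET, CountMatrix, LogMatrix

LEVELS = ("S", "G", "F")  # finest -> coarsest

__all__ = [
    "LEVELS",
    "TaxonDistanceMatrix",
    "PhyloHierarchy",
    "distances_from_tree",
    "build_hierarchy",
    "default_cut_heights",
    "aggregate_matrix",
]


@dataclass
class TaxonDistanceMatrix:
    """Symmetric non-negative pairwise distance matrix over taxa."""

    D: np.ndarray
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        m = len(self.taxon_ids)
        if self.D.shape != (m, m):
            raise ValueError("distance matrix shape does not match taxon ids")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.D)) > 1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.D < -1e-12):
            raise ValueError("negative distances")
        self.D = (self.D + self.D.T) / 2
        np.fill_diagonal(self.D, 0.0)

    def reorder(self, taxon_ids: list[str]) -> "TaxonDistanceMatrix":
        """Align to a given taxon ordering (must be a permutation)."""
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return TaxonDistanceMatrix(self.D[np.ix_(idx, idx)], list(taxon_ids))


@dataclass
class PhyloHierarchy:
    """Nested taxon partitions at levels "S" < "G" < "F".

    ``assignment[level]`` maps taxon_id -> cluster id; ``parent`` maps
    (level, cluster_id) -> cluster id at the next-coarser level; ``children``
    is the inverse.  Cluster membership is nested by construction.
    """

    taxon_ids: list[str]
    assignment: dict[str, dict[str, int]]
    parent: dict[tuple[str, int], int]
    children: dict[tuple[str, int], list[int]]
    cut_heights: tuple[float, float, float]

    def n_clusters(self, level: str) -> int:
        return len(set(self.assignment[level].values()))

    def labels(self, level: str) -> np.ndarray:
        """Cluster index per taxon, in taxon_ids order."""
        a = self.assignment[level]
        return np.array([a[t] for t in self.taxon_ids], dtype=int)


def distances_from_tree(tree: str | skbio.TreeNode) -> TaxonDistanceMatrix:
    """Patristic (branch-length path) distances between the leaves of a
    newick tree."""
    if isinstance(tree, str):
        tree = skbio.TreeNode.read(io.StringIO(tree))
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if len(set(names)) != len(names):
        dupes = {n for n in names if names.count(n) > 1}
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("tree has missing branch lengths")
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    return TaxonDistanceMatrix(np.asarray(dm.data, dtype=float), ids)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 0..k-1 ordered by smallest member index."""
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    return np.array([order[lab] for lab in labels], dtype=int)


def build_hierarchy(
    D: TaxonDistanceMatrix, cut_heights: tuple[float, float, float]
) -> PhyloHierarchy:
    """Complete-linkage dendrogram cut at three increasing heights.

    Within a cluster formed below height ``h`` the maximum pairwise
    distance is at most ``h`` (the complete-linkage guarantee); cutting one
    dendrogram at increasing heights makes the S/G/F partitions nested by
    construction.
    """
    h1, h2, h3 = cut_heights
    if not (0 < h1 < h2 < h3):
        raise ValueError("cut heights must be positive and strictly increasing")
    m = len(D.taxon_ids)
    if m < 2:
        labels = {lvl: {D.taxon_ids[0]: 0} for lvl in LEVELS}
        parent = {(lvl, 0): 0 for lvl in ("S", "G")}
        children = {("G", 0): [0], ("F", 0): [0]}
        return PhyloHierarchy(list(D.taxon_ids), labels, parent, children, cut_heights)
    Z = linkage(squareform(D.D, checks=False), method="complete")
    level_labels: dict[str, np.ndarray] = {}
    for lvl, h in zip(LEVELS, cut_heights):
        raw = fcluster(Z, t=h, criterion="distance")
        level_labels[lvl] = _relabel(raw)
    assignment = {
        lvl: {t: int(level_labels[lvl][i]) for i, t in enumerate(D.taxon_ids)}
        for lvl in LEVELS
    }
    parent: dict[tuple[str, int], int] = {}
    children: dict[tuple[str, int], list[int]] = {}
    for fine, coarse in (("S", "G"), ("G", "F")):
        for fl, cl in zip(level_labels[fine], level_labels[coarse]):
            key = (fine, int(fl))
            if key in parent:
                if parent[key] != int(cl):
                    raise RuntimeError("partitions not nested")  # unreachable
            else:
                parent[key] = int(cl)
                children.setdefault((coarse, int(cl)), []).append(int(fl))
    for key in children:
        children[key] = sorted(children[key])
    return PhyloHierarchy(list(D.taxon_ids), assignment, parent, children, cut_heights)


def default_cut_heights(
    D: TaxonDistanceMatrix, quantiles: tuple[float, float, float] = (0.25, 0.5, 0.75)
) -> tuple[float, float, float]:
    """Cut heights from quantiles of the off-diagonal distance
    distribution, nudged apart if ties collapse them."""
    q1, q2, q3 = quantiles
    if not (0 < q1 < q2 < q3 < 1):
        raise ValueError("quantiles must be strictly increasing in (0, 1)")
    m = len(D.taxon_ids)
    off = D.D[np.triu_indices(m, k=1)]
    if off.size == 0 or np.ptp(off) < 1e-12:
        raise ValueError(
            "all pairwise distances identical; supply explicit cut heights"
        )
    hs = list(np.quantile(off, [q1, q2, q3]))
    eps = 1e-9 * max(1.0, float(np.max(off)))
    for i in (1, 2):
        if hs[i] <= hs[i - 1]:
            hs[i] = hs[i - 1] + eps
    return (float(hs[0]), float(hs[1]), float(hs[2]))


def aggregate_matrix(
    normalized: CountMatrix,
    hierarchy: PhyloHierarchy,
    level: str,
    missing_mask: np.ndarray | None = None,
    offset: float = DEFAULT_OFFSET,
    library_size: float = DEFAULT_LIBRARY_SIZE,
) -> LogMatrix:
    """Per-level aggregated abundance matrix Y^h.

    Cluster abundance is the sum of member taxa normalized counts (masked
    member entries contribute zero), then log10(. + offset).  An aggregated
    entry is missing iff every member entry in that sample is missing.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    labels = hierarchy.labels(level)
    k = int(labels.max()) + 1
    n = normalized.shape[0]
    counts = normalized.values
    if missing_mask is None:
        missing_mask = np.zeros(counts.shape, dtype=bool)
    obs_counts = np.where(missing_mask, 0.0, counts)
    member = np.zeros((counts.shape[1], k))
    member[np.arange(counts.shape[1]), labels] = 1.0
    agg = obs_counts @ member
    all_missing = (missing_mask.astype(float) @ member) >= (
        np.ones((1, counts.shape[1])) @ member
    )
    values = np.log10(agg + offset)
    values[all_missing] = np.log10(offset)
    cluster_ids = [f"{level}{c}" for c in range(k)]
    return LogMatrix(
        values,
        list(normalized.sample_ids),
        cluster_ids,
        offset=offset,
        library_size=library_size,
        missing_mask=all_missing,
    )
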