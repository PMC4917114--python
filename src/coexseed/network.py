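"""Weighted co-expression network construction and module detection.

Unsigned weighted-correlation-network analysis: the adjacency is
|Pearson r|^beta (soft thresholding, beta = 6 by default), node
similarity is the unsigned topological overlap (TOM), genes are
average-linkage clustered on the 1 - TOM dissimilarity, and modules are
extracted from the dendrogram with a minimum-size rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ModuleAssignment

__all__ = [
    "soft_adjacency",
    "topological_overlap",
    "cluster_genes",
    "dynamic_tree_cut",
    "Dendrogram",
]


def soft_adjacency(values: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Soft-thresholded unsigned adjacency a_ij = |cor(x_i, x_j)|^beta.

    ``values`` is genes x samples. The diagonal is forced to 1. A gene
    with zero variance has no defined correlation and raises, naming the
    offending gene.
    """
    X = values.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = list(values.index[sd == 0][:5])
        raise ValueError(f"zero-variance gene(s): {bad}")
    corr = np.corrcoef(X)
    adj = np.abs(np.clip(corr, -1.0, 1.0)) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=values.index, columns=values.index)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j with
    L_ij = sum_{u not in {i,j}} a_iu a_uj and k_i = sum_{u != i} a_iu;
    TOM_ii = 1.
    """
    A = adjacency.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A  # zero diagonal excludes u in {i, j} automatically
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over genes (scipy linkage encoding)."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_genes(tom: pd.DataFrame) -> Dendrogram:
    """Average-linkage hierarchical clustering on the 1 - TOM dissimilarity."""
    if tom.shape[0] < 2:
        raise ValueError("need >= 2 genes to cluster")
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method="average")
    return Dendrogram(Z, [str(g) for g in tom.index])


def _gap_cut_height(heights: np.ndarray) -> float:
    """Cut at the midpoint of the largest gap between sorted merge heights.

    Only gaps whose upper edge lies in the top half of the height range
    are considered: the separation of interest is between the
    within-module merges and the background / between-module merges near
    the top of the tree, whereas gaps among the earliest merges are
    sampling noise. When the heights carry no gap structure (all merges
    at the same height) the cut is placed above the tree, yielding a
    single cluster.
    """
    hs = np.sort(heights)
    if len(hs) == 1:
        return float(hs[0]) + 1.0
    gaps = np.diff(hs)
    mid = hs[0] + 0.5 * (hs[-1] - hs[0])
    eligible = np.flatnonzero(hs[1:] >= mid)
    if len(eligible) == 0 or gaps[eligible].max() <= 1e-12:
        return float(hs[-1]) + 1.0
    i = int(eligible[np.argmax(gaps[eligible])])
    return float((hs[i] + hs[i + 1]) / 2.0)


def dynamic_tree_cut(
    dendrogram: Dendrogram,
    min_module_size: int = 20,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Extract modules from the dendrogram.

    By default the cut height is chosen adaptively at the largest gap in
    the merge-height sequence, which separates the low within-module
    merges from the high background/between-module merges; pass a numeric
    ``cut_height`` (on the 1 - TOM scale) to cut at a fixed height.
    Clusters smaller than ``min_module_size`` are left unassigned
    (label 0); surviving clusters are labelled 1..K by decreasing size,
    ties broken by the lexicographically smallest member gene.
    """
    Z = dendrogram.linkage
    genes = dendrogram.labels
    if cut_height is None:
        cut_height = _gap_cut_height(Z[:, 2])
    raw = fcluster(Z, t=cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    surviving = [
        members for members in clusters.values() if len(members) >= min_module_size
    ]
    surviving.sort(key=lambda members: (-len(members), min(members)))

    labels = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    for new_label, members in enumerate(surviving, start=1):
        labels.loc[members] = new_label
    return ModuleAssignment(labels, method="tree_cut")
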