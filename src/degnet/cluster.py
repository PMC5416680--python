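"""Sample-level Euclidean clustering and two-component PCA of count data.

Counts are placed on a log scale (log2 of normalized count + 1) before any
distance or PCA computation; the raw-count scale would let a handful of
highly expressed genes dominate every pairwise distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io import CountMatrix
from .de import estimate_size_factors


def transform_counts(cm: CountMatrix, size_factors: np.ndarray | None = None) -> pd.DataFrame:
    """log2(normalized count + 1), genes x samples."""
    if size_factors is None:
        size_factors = estimate_size_factors(cm)
    z = cm.counts / np.asarray(size_factors, float)[None, :]
    return pd.DataFrame(np.log2(z + 1.0), index=cm.gene_ids, columns=cm.sample_ids)


def euclidean_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance between samples (columns) over genes."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(matrix.to_numpy().T, metric="euclidean"))
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


class ClusterTree:
    """Agglomerative average-linkage tree over samples.

    merges is the scipy linkage matrix (pair indices, merge height, cluster
    size); heights are non-decreasing for average linkage on a metric
    distance. Ties are broken deterministically toward the lowest index pair.
    """

    def __init__(self, merges: np.ndarray, labels: list[str]):
        self.merges = merges
        self.labels = list(labels)

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]

    def newick(self) -> str:
        root = hierarchy.to_tree(self.merges)
        if root.is_leaf():
            return f"{self.labels[root.id]};"

        def walk(node, parent_dist) -> str:
            length = parent_dist - node.dist if parent_dist is not None else 0.0
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_dist:.6g}"
            inner = f"({walk(node.get_left(), node.dist)},{walk(node.get_right(), node.dist)})"
            if parent_dist is None:
                return inner
            return f"{inner}:{length:.6g}"

        return walk(root, None) + ";"

    def cut(self, n_clusters: int) -> dict[str, int]:
        assign = hierarchy.fcluster(self.merges, t=n_clusters, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}


def hierarchical_cluster(dist: pd.DataFrame, linkage: str = "average") -> ClusterTree:
    """Cluster samples from a distance matrix ("clustered on shorter distances")."""
    if dist.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if linkage != "average":
        raise ValueError("only average linkage is supported")
    condensed = squareform(dist.to_numpy(), checks=False)
    merges = hierarchy.linkage(condensed, method="average")
    return ClusterTree(merges, list(dist.index.astype(str)))


def pca_two_components(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-component PCA of samples in gene space.

    Columns (samples) are the observations; each gene is centered across
    samples. Returns per-sample (PC1, PC2) scores and the explained-variance
    fractions, PC1 >= PC2. Sign convention: the largest-magnitude gene
    loading of each component is positive.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for a two-component PCA")
    x = matrix.to_numpy().T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise ValueError("zero-variance input; PCA is undefined")
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    total_var = np.sum(sv**2)
    scores = u[:, :2] * sv[:2]
    for c in range(2):
        pivot = np.argmax(np.abs(vt[c]))
        if vt[c, pivot] < 0:
            vt[c] *= -1.0
            scores[:, c] *= -1.0
    explained = (sv[:2] ** 2) / total_var
    out = pd.DataFrame(scores, index=matrix.columns, columns=["PC1", "PC2"])
    return out, explained
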