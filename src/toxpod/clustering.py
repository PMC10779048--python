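"""Hierarchical clustering of pathway z-score profiles.

The sample × pathway activation z-score matrix is zero-filled wherever a
pathway is non-significant in a sample or carries no z-score, so the matrix
is complete.  Similarity between profiles is the uncentered Pearson
correlation Σxy/√(Σx²·Σy²) (cosine of the raw vectors, no mean-centering);
distance = 1 − similarity.  Agglomeration uses unweighted average linkage
(UPGMA).  Sample rows that are entirely zero have undefined similarity and
are excluded from clustering and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from toxpod.enrichment import EnrichmentResult

__all__ = [
    "ZScoreMatrix",
    "Dendrogram",
    "build_zscore_matrix",
    "uncentered_pearson",
    "pairwise_uncentered_distance",
    "average_linkage",
    "cut_dendrogram",
    "cluster_samples",
]


@dataclass
class ZScoreMatrix:
    """Complete samples × pathways matrix of activation z-scores."""

    values: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def pathways(self) -> list[str]:
        return list(self.values.columns)

    def nonzero_rows(self) -> pd.DataFrame:
        mask = (self.values != 0).any(axis=1)
        return self.values[mask]

    def zero_rows(self) -> list[str]:
        mask = (self.values == 0).all(axis=1)
        return list(self.values.index[mask])


@dataclass
class Dendrogram:
    """Average-linkage merge tree over labelled leaves.

    ``linkage`` is a SciPy linkage matrix (n−1 merges, nondecreasing
    heights); ``labels`` names the leaves in input order.
    """

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape[0] != n - 1:
            raise ValueError("linkage must have n-1 merges for n leaves")

    def to_newick(self) -> str:
        """Serialize the merge tree with branch lengths to Newick text."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def build_zscore_matrix(results: list[EnrichmentResult]) -> ZScoreMatrix:
    """Assemble the zero-filled sample × pathway z-score matrix.

    A cell holds the activation z only when the pathway is significantly
    enriched in that sample AND a z-score exists; otherwise 0.  Split
    fold-change sublists become separate rows (``sample|low`` etc.).
    Duplicate (sample, pathway) entries raise.
    """
    samples: list[str] = []
    pathways: list[str] = []
    cells: dict[tuple[str, str], float] = {}
    for r in results:
        key = (r.row_label, r.pathway)
        if key in cells:
            raise ValueError(f"duplicate enrichment entry for {key}")
        if r.row_label not in samples:
            samples.append(r.row_label)
        if r.pathway not in pathways:
            pathways.append(r.pathway)
        z = r.z if (r.significant and r.z is not None) else 0.0
        cells[key] = z
    mat = pd.DataFrame(0.0, index=samples, columns=pathways)
    for (s, p), z in cells.items():
        mat.loc[s, p] = z
    return ZScoreMatrix(mat)


def uncentered_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Uncentered Pearson similarity Σxy/√(Σx²·Σy²), in [−1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = np.sqrt((x**2).sum())
    ny = np.sqrt((y**2).sum())
    if nx == 0 or ny == 0:
        raise ValueError("uncentered Pearson undefined for a zero vector")
    return float(np.clip((x * y).sum() / (nx * ny), -1.0, 1.0))


def pairwise_uncentered_distance(rows: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Square matrix of 1 − uncentered-Pearson over the rows."""
    x = np.asarray(rows, dtype=float)
    norms = np.sqrt((x**2).sum(axis=1))
    if np.any(norms == 0):
        raise ValueError("zero rows must be excluded before clustering")
    sim = (x @ x.T) / np.outer(norms, norms)
    sim = np.clip(sim, -1.0, 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def average_linkage(
    distances: np.ndarray | pd.DataFrame, labels: list[str] | None = None
) -> Dendrogram:
    """UPGMA agglomeration of a symmetric zero-diagonal distance matrix."""
    if isinstance(distances, pd.DataFrame):
        if labels is None:
            labels = list(distances.index)
        distances = distances.to_numpy(dtype=float)
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    if labels is None:
        labels = [str(i) for i in range(d.shape[0])]
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(z, list(labels))


def cut_dendrogram(tree: Dendrogram, k: int) -> pd.Series:
    """Cut the tree into k groups by removing the k−1 highest merges."""
    n = len(tree.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    flat = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    return pd.Series(flat, index=tree.labels, name="cluster")


def cluster_samples(
    zmat: ZScoreMatrix, k: int = 4
) -> tuple[Dendrogram, pd.Series, list[str]]:
    """Cluster sample z-score profiles; all-zero rows are set aside.

    Returns (dendrogram, cluster labels, excluded all-zero samples).  The
    default four-group cut matches the typical number of metal-specific
    response families in these experiments.
    """
    rows = zmat.nonzero_rows()
    excluded = zmat.zero_rows()
    if len(rows) < 2:
        raise ValueError("need >= 2 nonzero sample rows to cluster")
    k = min(k, len(rows))
    d = pairwise_uncentered_distance(rows)
    tree = average_linkage(d, list(rows.index))
    labels = cut_dendrogram(tree, k)
    return tree, labels, excluded
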