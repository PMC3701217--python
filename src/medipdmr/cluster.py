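"""Hierarchical clustering (UPGMA) and ordered-matrix export.

Expression matrices and PeakScore matrices are clustered with Euclidean
distance and average linkage; the purity helper quantifies how well a
two-way cut of the sample dendrogram recovers the treated/control split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class Dendrogram:
    """Agglomerative clustering result.

    ``linkage`` is the standard (n-1, 4) merge matrix: each row holds the two
    merged node ids, the merge height, and the merged cluster size.  Leaves
    are numbered 0..n-1 in input order; internal nodes continue from n.
    """

    linkage: np.ndarray
    labels: tuple
    method: str = "average"
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage shape does not match leaf count")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        """(node_a, node_b, height) triples in merge order."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    @property
    def leaf_order(self) -> list:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster ids (1..k) per leaf, in input order."""
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string with branch lengths (parent height - child height)."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        for row, (a, b, h, _) in enumerate(self.linkage):
            heights[n + row] = float(h)

        def render(node: int, parent_h: float) -> str:
            if node < n:
                name = str(self.labels[node]).replace(" ", "_")
                return f"{name}:{parent_h:.6g}"
            a, b, h, _ = self.linkage[node - n]
            inner = f"({render(int(a), h)},{render(int(b), h)})"
            return f"{inner}:{parent_h - h:.6g}"

        root = n + len(self.linkage) - 1
        a, b, h, _ = self.linkage[-1]
        return f"({render(int(a), h)},{render(int(b), h)});" if root >= n else ";"


def hcluster(
    matrix,
    axis: int = 0,
    metric: str = "euclidean",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of matrix rows (axis=0) or columns (axis=1).

    Average linkage on Euclidean distance reproduces UPGMA.  SciPy's
    nearest-neighbour-chain agglomeration is deterministic; equal-distance
    ties resolve to the lowest-index pair.

    Raises
    ------
    ValueError
        For NaN/inf values or fewer than two items.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index if axis == 0 else matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = list(range(X.shape[0] if axis == 0 else X.shape[1]))
    if axis == 1:
        X = X.T
    if X.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in matrix")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    return Dendrogram(Z, tuple(labels), method=linkage, metric=metric)


def cluster_purity(dendro: Dendrogram, labels) -> float:
    """Two-cluster purity of a dendrogram against binary sample labels.

    The tree is cut into two flat clusters and compared with the labels under
    the best of the two possible cluster-to-label assignments; the result
    lies in [0.5, 1] for balanced designs (1.0 = perfect separation).

    Raises
    ------
    ValueError
        If the labels have more than two levels or the length mismatches.
    """
    labels = np.asarray(labels)
    if len(labels) != dendro.n_leaves:
        raise ValueError("one label per leaf required")
    levels = np.unique(labels)
    if len(levels) > 2:
        raise ValueError("cluster_purity requires binary labels")
    if len(levels) == 1:
        return 1.0
    cut = dendro.cut(2)
    y = (labels == levels[1]).astype(int)
    c = (cut == 2).astype(int)
    agree = np.mean(y == c)
    return float(max(agree, 1.0 - agree))


def ordered_matrix(
    matrix: pd.DataFrame,
    row_dendro: Dendrogram | None = None,
    col_dendro: Dendrogram | None = None,
) -> pd.DataFrame:
    """Reorder a matrix by dendrogram leaf order (heat-map export)."""
    out = matrix
    if row_dendro is not None:
        out = out.loc[row_dendro.leaf_order]
    if col_dendro is not None:
        out = out[col_dendro.leaf_order]
    return out
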