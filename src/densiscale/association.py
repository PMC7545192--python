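"""Similarity, distance and hierarchical clustering over DSAM vectors.

Pairs of DSAM vectors (two indicators across regions, or two regions across
indicators after transposing) are compared with one of five similarity
measures — Pearson, Spearman, Kendall (tau-b), cosine, or Jaccard on
sign-binarised residuals — and turned into a distance

    delta_ij = sqrt(2 (1 - sm_ij)),

the chord distance of the unit-sphere embedding (0 for identical, sqrt(2)
for orthogonal, 2 for opposite).  Agglomerative clustering on that distance
yields the indicator and region dendrograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .dsam import DsamMatrix

MEASURES = ("pearson", "spearman", "kendall", "cosine", "jaccard")


class UnknownMeasureError(ValueError):
    pass


@dataclass
class SimilarityMatrix:
    labels: list[str]
    measure: str
    sm: pd.DataFrame  # symmetric, diagonal 1, values in [-1, 1]
    n_pairs: pd.DataFrame  # per-cell count of complete observations

    def write_csv(self, path: str | Path) -> None:
        self.sm.to_csv(path)


def _pairwise_cosine(z: pd.DataFrame, min_pairs: int) -> pd.DataFrame:
    cols = list(z.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    arr = z.to_numpy(float)
    finite = np.isfinite(arr)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            both = finite[:, i] & finite[:, j]
            if both.sum() < min_pairs:
                val = np.nan
            else:
                a, b = arr[both, i], arr[both, j]
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                val = np.nan if na == 0 or nb == 0 else float(a @ b / (na * nb))
            out.iat[i, j] = out.iat[j, i] = val
    return out


def _pairwise_jaccard(z: pd.DataFrame, min_pairs: int) -> pd.DataFrame:
    # sign binarisation: above scaling expectation (z > 0) -> 1
    cols = list(z.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    arr = z.to_numpy(float)
    finite = np.isfinite(arr)
    pos = arr > 0
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            both = finite[:, i] & finite[:, j]
            if both.sum() < min_pairs:
                val = np.nan
            else:
                a, b = pos[both, i], pos[both, j]
                union = (a | b).sum()
                val = 1.0 if union == 0 else float((a & b).sum() / union)
            out.iat[i, j] = out.iat[j, i] = val
    return out


def similarity_matrix(
    zm: DsamMatrix | pd.DataFrame,
    measure: str = "pearson",
    min_pairs: int = 3,
) -> SimilarityMatrix:
    """Pairwise-complete similarity between the columns of a DSAM matrix.

    For indicator similarity pass the DSAM matrix directly; for region
    similarity pass its :meth:`~densiscale.dsam.DsamMatrix.transpose_view`.
    Cells with fewer than ``min_pairs`` complete observations are missing.
    """
    if measure not in MEASURES:
        raise UnknownMeasureError(f"unknown measure {measure!r}; choose from {MEASURES}")
    z = zm.z if isinstance(zm, DsamMatrix) else pd.DataFrame(zm)
    notna = z.notna().astype(int)
    n_pairs = notna.T @ notna
    if measure in ("pearson", "spearman", "kendall"):
        sm = z.corr(method=measure, min_periods=min_pairs)
    elif measure == "cosine":
        sm = _pairwise_cosine(z, min_pairs)
    else:
        sm = _pairwise_jaccard(z, min_pairs)
    sm = (sm + sm.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(sm.values, 1.0)
    sm = sm.clip(-1.0, 1.0)
    return SimilarityMatrix(labels=list(z.columns), measure=measure, sm=sm, n_pairs=n_pairs)


def similarity_to_distance(sm: SimilarityMatrix | pd.DataFrame, atol: float = 1e-9) -> pd.DataFrame:
    """Chord distance delta = sqrt(2 (1 - sm)); 0 on the diagonal, range [0, 2]."""
    m = sm.sm if isinstance(sm, SimilarityMatrix) else pd.DataFrame(sm)
    vals = m.to_numpy(float)
    finite = np.isfinite(vals)
    if np.any((vals[finite] < -1 - atol) | (vals[finite] > 1 + atol)):
        raise ValueError("similarity values outside [-1, 1]")
    delta = np.sqrt(2.0 * np.clip(1.0 - vals, 0.0, None))
    np.fill_diagonal(delta, 0.0)
    return pd.DataFrame(delta, index=m.index, columns=m.columns)


@dataclass
class ClusterResult:
    """Agglomerative merge tree over a set of labelled items."""

    labels: list[str]
    method: str
    linkage_matrix: np.ndarray

    def cut(self, k: int) -> pd.Series:
        """Cluster assignment (1..k) from cutting the tree at k groups."""
        if not 1 <= k <= len(self.labels):
            raise ValueError(f"k={k} outside [1, {len(self.labels)}]")
        lab = sch.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(lab, index=self.labels, name="cluster")

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(sch.cophenet(self.linkage_matrix))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        """Dendrogram in Newick text form (branch lengths from merge heights)."""
        tree = sch.to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});" if not tree.is_leaf() else f"({self.labels[tree.id]});"


def hierarchical_cluster(
    dist: pd.DataFrame,
    method: str = "complete",
    k: int | None = None,
) -> ClusterResult | tuple[ClusterResult, pd.Series]:
    """Agglomerative clustering of a symmetric distance matrix.

    ``method`` is any scipy linkage ('complete' default, 'average', 'ward',
    ...).  When ``k`` is given the tree is also cut and the assignment
    returned alongside the tree.
    """
    dist = pd.DataFrame(dist)
    vals = dist.to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("distance matrix contains missing values")
    condensed = squareform(vals, checks=False)
    Z = sch.linkage(condensed, method=method)
    result = ClusterResult(labels=list(dist.index), method=method, linkage_matrix=Z)
    if k is None:
        return result
    return result, result.cut(k)
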