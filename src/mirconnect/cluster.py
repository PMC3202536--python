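"""Functional clustering of miRNAs by overlap of their top correlator genes.

Two miRNAs whose top correlator lists share many genes plausibly act on the
same biological program.  The pairwise percent identity of overlapping genes
forms a square matrix; its rows are embedded as vectors, pairwise Euclidean
distances feed complete-linkage agglomeration, and the tree is cut so that
within every reported cluster each pair of miRNAs shares more than a threshold
percentage (12.5% by default) of their correlators.  A centered PCA of the
overlap matrix provides a 2-D summary of the same structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "OverlapMatrix",
    "ClusterAssignment",
    "overlap_percent",
    "overlap_matrix",
    "functional_clusters",
    "pca_scores",
    "dendrogram_newick",
    "roman",
    "DEFAULT_SHARE_THRESHOLD",
]

DEFAULT_SHARE_THRESHOLD = 12.5  #: percent of shared correlators defining a cluster

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


@dataclass
class OverlapMatrix:
    """miRNA x miRNA percent identity of overlapping correlated genes."""

    mirnas: list[str]
    matrix: np.ndarray  # square, symmetric, entries in [0, 100]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        n = len(self.mirnas)
        if self.matrix.shape != (n, n):
            raise ValueError("overlap matrix must be square and match the miRNA list")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("overlap matrix must be symmetric")
        if self.matrix.min() < 0 or self.matrix.max() > 100:
            raise ValueError("overlap percentages must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.mirnas, columns=self.mirnas)


@dataclass
class ClusterAssignment:
    """miRNA -> cluster label (Roman numerals in dendrogram order)."""

    labels: dict[str, str]
    cut_height: float
    share_threshold: float

    def members(self, label: str) -> list[str]:
        return [m for m, l in self.labels.items() if l == label]

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def overlap_percent(list_a: Sequence[str], list_b: Sequence[str], denom: int) -> float:
    """100 x |A intersect B| / denom, for two top-N correlator lists."""
    if denom <= 0:
        raise ValueError("denom must be positive")
    return 100.0 * len(set(list_a) & set(list_b)) / denom


def overlap_matrix(top_lists: Mapping[str, Sequence[str]], denom: int) -> OverlapMatrix:
    """Symmetric matrix of pairwise overlap percentages, diagonal = 100."""
    mirnas = list(top_lists)
    sets = [set(top_lists[m]) for m in mirnas]
    n = len(mirnas)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = 100.0 * len(sets[i] & sets[j]) / denom
            mat[i, j] = mat[j, i] = v
    return OverlapMatrix(mirnas=mirnas, matrix=mat)


def _linkage(mat: OverlapMatrix) -> np.ndarray:
    # distances between matrix ROWS (vectors of overlap percentages)
    return hierarchy.complete(pdist(mat.matrix, metric="euclidean"))


def functional_clusters(
    mat: OverlapMatrix,
    share_threshold_percent: float = DEFAULT_SHARE_THRESHOLD,
    cut_height: float | None = None,
) -> ClusterAssignment:
    """Cut the complete-linkage tree so every within-cluster pair shares more
    than ``share_threshold_percent`` of its correlators.

    The stated percentage does not translate directly into a Euclidean cut
    height, so candidate heights are scanned from the top of the tree down and
    the largest height whose clusters all satisfy the pairwise-overlap
    condition is used; if none does, every miRNA becomes a singleton.  Raising
    the threshold can only split clusters, never merge them.
    """
    n = len(mat.mirnas)
    if n < 2:
        raise ValueError("need at least 2 miRNAs to cluster")
    Z = _linkage(mat)
    chosen: np.ndarray | None = None
    chosen_height = 0.0
    if cut_height is not None:
        # raw-height alternative to the overlap-percent cut rule
        chosen = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
        chosen_height = float(cut_height)
    else:
        for h in np.unique(Z[:, 2])[::-1]:
            flat = hierarchy.fcluster(Z, t=h, criterion="distance")
            if _all_pairs_share(mat.matrix, flat, share_threshold_percent):
                chosen = flat
                chosen_height = float(h)
                break
    if chosen is None:
        chosen = np.arange(1, n + 1)
        chosen_height = 0.0
    # label clusters with Roman numerals in dendrogram leaf order
    leaves = hierarchy.leaves_list(Z)
    seen: dict[int, str] = {}
    for leaf in leaves:
        cid = int(chosen[leaf])
        if cid not in seen:
            seen[cid] = roman(len(seen) + 1)
    labels = {mat.mirnas[i]: seen[int(chosen[i])] for i in range(n)}
    return ClusterAssignment(
        labels=labels, cut_height=chosen_height,
        share_threshold=share_threshold_percent,
    )


def _all_pairs_share(matrix: np.ndarray, flat: np.ndarray, threshold: float) -> bool:
    for cid in np.unique(flat):
        idx = np.flatnonzero(flat == cid)
        if idx.size < 2:
            continue
        sub = matrix[np.ix_(idx, idx)]
        off = sub[~np.eye(idx.size, dtype=bool)]
        if off.min() <= threshold:
            return False
    return True


def pca_scores(mat: OverlapMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered (unscaled) PCA of the overlap-matrix rows.

    Returns per-miRNA scores on the top two components and the explained
    variance fractions.  Signs are fixed so the largest-magnitude loading of
    each component is positive.  If the centered matrix has rank < 2 the
    available components are returned with a warning.
    """
    X = mat.matrix - mat.matrix.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int((S > tol).sum())
    k = min(2, rank)
    if k < 2:
        warnings.warn(f"overlap matrix has rank {rank}; returning {k} component(s)")
    total_var = float((S**2).sum())
    cols, ev = {}, []
    for i in range(k):
        load = Vt[i]
        sign = 1.0 if load[np.argmax(np.abs(load))] >= 0 else -1.0
        cols[f"PC{i + 1}"] = sign * U[:, i] * S[i]
        ev.append((S[i] ** 2) / total_var if total_var > 0 else 0.0)
    if k == 0:
        cols["PC1"] = np.zeros(len(mat.mirnas))
        ev.append(0.0)
    df = pd.DataFrame(cols, index=mat.mirnas)
    return df, np.asarray(ev)


def dendrogram_newick(mat: OverlapMatrix) -> str:
    """The complete-linkage tree of the overlap matrix in Newick format."""
    Z = _linkage(mat)
    tree = hierarchy.to_tree(Z)
    names = mat.mirnas

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
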