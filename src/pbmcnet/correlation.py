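"""Pairwise co-expression statistics and hierarchical clustering.

Pearson correlations between gene expression profiles with two-sided
p-values from the t-transform ``t = r*sqrt((n-2)/(1-r^2))``, a single
global Bonferroni correction over all G(G-1)/2 pairs, and complete-linkage
clustering of the standardized profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .qpcr import ExpressionMatrix

__all__ = [
    "CorrelationResult",
    "correlation_matrix",
    "significant_pairs",
    "Dendrogram",
    "hierarchical_clustering",
]


@dataclass
class CorrelationResult:
    """Symmetric Pearson r matrix with raw and Bonferroni-adjusted p-values.

    ``n_tests = G(G-1)/2`` and ``p_adj = min(1, p_raw * n_tests)`` (one global
    family-wise correction over the full matrix).  ``n_obs`` holds the number
    of pairwise-complete subjects used for each pair.
    """

    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n_obs: pd.DataFrame
    n_tests: int

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.r.index)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("correlation: fewer than 3 pairwise-complete subjects")
    xv, yv = x[mask], y[mask]
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p), n


def correlation_matrix(m: ExpressionMatrix) -> CorrelationResult:
    """All-pairs Pearson correlations of gene expression profiles.

    Requires >= 3 subjects; a zero-variance gene raises ``ValueError``.
    Pearson r is affine-invariant, so RCN and z-scored inputs give the same
    coefficients.  Missing values are handled pairwise-complete.
    """
    vals = m.values
    genes = list(vals.index)
    G = len(genes)
    if vals.shape[1] < 3:
        raise ValueError("correlation_matrix: need at least 3 subjects")
    sd = vals.std(axis=1, ddof=1)
    flat = list(vals.index[(sd == 0) | sd.isna()])
    if flat:
        raise ValueError(f"correlation_matrix: zero-variance genes: {flat}")

    arr = vals.to_numpy(dtype=float)
    r = np.eye(G)
    p = np.zeros((G, G))
    nobs = np.full((G, G), vals.shape[1], dtype=int)
    n_tests = G * (G - 1) // 2
    for i, j in combinations(range(G), 2):
        rij, pij, nij = _pearson_with_p(arr[i], arr[j])
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij
        nobs[i, j] = nobs[j, i] = nij
    p_adj = np.minimum(1.0, p * n_tests)
    np.fill_diagonal(p_adj, 0.0)
    mk = lambda a: pd.DataFrame(a, index=genes, columns=genes)
    return CorrelationResult(mk(r), mk(p), mk(p_adj), mk(nobs), n_tests)


def significant_pairs(c: CorrelationResult, alpha: float) -> set[frozenset[str]]:
    """Gene pairs with Bonferroni-adjusted p below ``alpha`` (strict)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("significant_pairs: alpha must be in (0, 1)")
    genes = c.genes
    out: set[frozenset[str]] = set()
    for a, b in combinations(genes, 2):
        if c.p_adj.loc[a, b] < alpha:
            out.add(frozenset((a, b)))
    return out


@dataclass
class Dendrogram:
    """A binary merge tree from agglomerative clustering.

    ``Z`` is a scipy linkage matrix over ``labels`` (leaf order = input gene
    order); heights are non-decreasing along merges for complete linkage.
    """

    Z: np.ndarray
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def merge_heights(self) -> np.ndarray:
        return self.Z[:, 2].copy()

    def to_newick(self) -> str:
        """Serialize the merge tree as a Newick string with branch lengths."""
        tree = to_tree(self.Z)

        def recurse(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.10g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.10g}"

        root = tree
        left = recurse(root.left, root.dist)
        right = recurse(root.right, root.dist)
        return f"({left},{right}):0;"


def hierarchical_clustering(
    m: ExpressionMatrix,
    method: str = "complete",
    metric: str = "euclidean",
) -> Dendrogram:
    """Complete-linkage clustering of gene profiles.

    ``metric`` is ``"euclidean"`` (on z-score profiles, the default — for
    standardized data Euclidean distance is monotone in ``1 - r``) or
    ``"correlation"`` (``1 - r`` directly).
    """
    if method != "complete":
        raise ValueError("hierarchical_clustering: only complete linkage is supported")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"hierarchical_clustering: unknown metric {metric!r}")
    vals = m.values
    if vals.shape[0] < 2:
        raise ValueError("hierarchical_clustering: need at least 2 genes")
    X = vals.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("hierarchical_clustering: missing values not supported")
    D = pdist(X, metric=metric)
    Z = linkage(D, method="complete")
    return Dendrogram(Z, tuple(vals.index))
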