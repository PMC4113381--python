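"""Exploratory sample-structure analyses.

PCA of samples over gene-centered log2 expression, average-linkage
hierarchical clustering of samples on per-gene z-scores of a chosen gene
subset (typically the genes differentially expressed between two zones),
and the z-score matrix used for heat-map display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix, fold_symbol

__all__ = ["PcaResult", "DendrogramResult", "pca_samples", "cluster_samples",
           "zscore_matrix"]


@dataclass
class PcaResult:
    """Sample scores and explained-variance fractions of a sample PCA."""

    scores: pd.DataFrame          # samples x components
    explained_fraction: np.ndarray

    def __post_init__(self) -> None:
        frac = np.asarray(self.explained_fraction, dtype=float)
        if (frac < -1e-12).any():
            raise ValueError("negative explained-variance fraction")
        if not np.isclose(frac.sum(), 1.0, atol=1e-9):
            raise ValueError("explained-variance fractions must sum to 1")
        if (np.diff(frac) > 1e-12).any():
            raise ValueError("fractions must be non-increasing")
        self.explained_fraction = frac

    def retained(self, n_components: int) -> float:
        """Fraction of total variance kept by the first n components."""
        return float(self.explained_fraction[:n_components].sum())


@dataclass
class DendrogramResult:
    """Agglomerative merge sequence for a set of samples."""

    sample_ids: list
    merges: list          # (cluster_id_1, cluster_id_2) per merge
    heights: np.ndarray
    leaf_order: list
    linkage_matrix: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.merges) != n - 1:
            raise ValueError("need exactly n-1 merges for n samples")
        if (np.asarray(self.heights) < 0).any():
            raise ValueError("merge heights must be non-negative")

    def to_tree_dict(self) -> dict:
        """Nested JSON-able tree (leaves carry sample ids)."""
        nodes = [{"leaf": sid} for sid in self.sample_ids]
        for (i, j), h in zip(self.merges, self.heights):
            nodes.append({"height": float(h),
                          "children": [nodes[int(i)], nodes[int(j)]]})
        return nodes[-1]


def _select_genes(matrix: ExpressionMatrix, gene_subset) -> pd.DataFrame:
    if gene_subset is None:
        return matrix.values
    wanted = {fold_symbol(g) for g in gene_subset}
    keep = [g for g in matrix.values.index if fold_symbol(g) in wanted]
    if not keep:
        raise ValueError("gene subset matches no genes in the matrix")
    return matrix.values.loc[keep]


def pca_samples(matrix: ExpressionMatrix, gene_subset=None,
                standardize: bool = False) -> PcaResult:
    """PCA of samples over gene-centered (optionally standardized) data.

    Genes are variables, samples observations; each gene is centered
    (``standardize=True`` additionally divides by its sd,
    correlation-mode).  Scores are the projections onto the principal
    axes; fractions are eigenvalues over total variance.
    """
    values = _select_genes(matrix, gene_subset)
    X = values.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    total_var = np.var(X - X.mean(axis=0), axis=0, ddof=1).sum()
    if total_var == 0:
        raise ValueError("zero total variance across samples")
    pca = PCA(n_components=None)  # centers each gene internally
    scores = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    sample_ids = list(map(str, values.columns))
    return PcaResult(pd.DataFrame(scores, index=sample_ids, columns=cols),
                     frac / frac.sum())


def zscore_matrix(matrix: ExpressionMatrix, gene_subset=None):
    """Per-gene z-scores across samples, for heat-map display.

    Returns ``(z, constant_genes)``: genes with zero variance get an
    all-zero row and are reported in ``constant_genes``.
    """
    values = _select_genes(matrix, gene_subset)
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    sd[sd == 0] = 1.0
    z = (arr - mean) / sd
    z[constant, :] = 0.0
    zdf = pd.DataFrame(z, index=values.index, columns=values.columns)
    return zdf, [str(g) for g in values.index[constant]]


def cluster_samples(matrix: ExpressionMatrix, gene_subset=None,
                    metric: str = "euclidean", linkage: str = "average",
                    zscore: bool = True) -> DendrogramResult:
    """Agglomerative clustering of samples on (z-scored) expression.

    Samples are ordered lexicographically by id before linkage so ties in
    the distance matrix break deterministically.  The default pairs
    Euclidean distance on per-gene z-scores with average linkage.
    """
    if zscore:
        values, _ = zscore_matrix(matrix, gene_subset)
    else:
        values = _select_genes(matrix, gene_subset)
    order = sorted(map(str, values.columns))
    X = values[order].to_numpy(dtype=float).T
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    Z = hierarchy.linkage(X, method=linkage, metric=metric)
    merges = [(int(a), int(b)) for a, b, _h, _n in Z]
    heights = Z[:, 2].copy()
    leaves = [order[i] for i in hierarchy.leaves_list(Z)]
    return DendrogramResult(order, merges, heights, leaves, linkage_matrix=Z)
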