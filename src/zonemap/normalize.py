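"""Array normalization and probe summarization.

Implements the two summarization components of robust multi-array average
that operate on a probe-by-sample intensity matrix: quantile normalization
(force every array onto the common per-rank mean distribution) and Tukey
median polish (per-gene additive decomposition of log2 probe intensities
into probe and sample effects), plus the log2 transform.  Probe-level
background correction is out of scope: the input is an already-extracted
probe intensity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "ProbeMatrix",
    "quantile_normalize",
    "median_polish",
    "log2_transform",
    "summarize_probes",
    "QuantileNormalizer",
]


@dataclass
class ProbeMatrix:
    """Linear-scale probe intensities with a probe -> gene map."""

    values: pd.DataFrame
    probe_gene: pd.Series

    def __post_init__(self) -> None:
        self.probe_gene = pd.Series(self.probe_gene)
        missing = [p for p in self.values.index if p not in self.probe_gene.index]
        if missing:
            raise ValueError(f"probes without a gene mapping: {missing[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr <= 0).any():
            raise ValueError("probe intensities must be finite and > 0")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.values.index:
            seen.setdefault(str(self.probe_gene[p]))
        return list(seen)

    def gene_block(self, gene: str) -> pd.DataFrame:
        probes = [p for p in self.values.index if str(self.probe_gene[p]) == str(gene)]
        return self.values.loc[probes]


def _quantile_normalize_columns(arr: np.ndarray) -> np.ndarray:
    """Columns mapped onto the per-rank cross-column mean distribution.

    Ties within a column receive the mean of the reference values at the
    tied rank positions.
    """
    ref = np.sort(arr, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(arr, dtype=float)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        rmin = rankdata(col, method="min").astype(int)
        rmax = rankdata(col, method="max").astype(int)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    return out


def quantile_normalize(matrix):
    """Quantile-normalize a genes x samples matrix across its columns.

    After normalization every column holds the identical value multiset:
    the per-rank means of the column-sorted input.  Shape and within-column
    rank order are preserved; DataFrame input keeps its labels.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    arr = np.asarray(matrix.to_numpy() if is_df else matrix, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("need a non-empty 2-D matrix")
    out = _quantile_normalize_columns(arr)
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def median_polish(block, tol: float = 1e-6, max_iter: int = 10):
    """Tukey median polish of one gene's probes x samples block.

    Alternately sweeps row (probe) and column (sample) medians out of the
    residuals until the largest absolute change in any effect drops below
    ``tol`` or ``max_iter`` full sweeps are done.  Returns ``(grand,
    row_effects, col_effects, residuals)`` with the exact reconstruction
    ``block = grand + row_effects[:, None] + col_effects[None, :] +
    residuals``; the per-sample gene summary is ``grand + col_effects``.
    """
    arr = np.asarray(block, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0:
        raise ValueError("empty block")
    resid = arr.copy()
    grand = 0.0
    row = np.zeros(arr.shape[0])
    col = np.zeros(arr.shape[1])
    for _ in range(max_iter):
        delta = 0.0
        rmed = np.median(resid, axis=1)
        row += rmed
        resid -= rmed[:, None]
        shift = np.median(col)
        grand += shift
        col -= shift
        delta = max(delta, np.abs(rmed).max(), abs(shift))

        cmed = np.median(resid, axis=0)
        col += cmed
        resid -= cmed[None, :]
        shift = np.median(row)
        grand += shift
        row -= shift
        delta = max(delta, np.abs(cmed).max(), abs(shift))
        if delta < tol:
            break
    # exact reconstruction by construction: resid = arr - grand - row - col
    return grand, row, col, resid


def log2_transform(matrix, offset: float = 0.0):
    """Elementwise log2(value + offset); all shifted values must be > 0."""
    is_df = isinstance(matrix, pd.DataFrame)
    arr = np.asarray(matrix.to_numpy() if is_df else matrix, dtype=float) + offset
    if (arr <= 0).any():
        raise ValueError("log2_transform requires value + offset > 0 everywhere")
    out = np.log2(arr)
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def summarize_probes(probes: ProbeMatrix, quantile: bool = True,
                     tol: float = 1e-6, max_iter: int = 10) -> pd.DataFrame:
    """Probe matrix -> one log2 expression value per gene and sample.

    Pipeline: (optional) quantile normalization of the linear intensities
    across arrays, log2 transform, then median polish per gene with the
    per-sample summary ``grand + column effect``.
    """
    values = probes.values
    if quantile:
        values = quantile_normalize(values)
    logged = log2_transform(values)
    genes = probes.genes
    out = np.empty((len(genes), logged.shape[1]))
    gene_of = probes.probe_gene.astype(str)
    groups = {g: [] for g in genes}
    for p in logged.index:
        groups[gene_of[p]].append(p)
    for i, g in enumerate(genes):
        grand, _row, colfx, _res = median_polish(
            logged.loc[groups[g]].to_numpy(), tol=tol, max_iter=max_iter)
        out[i] = grand + colfx
    return pd.DataFrame(out, index=genes, columns=logged.columns)


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer matching sample rows to a reference distribution.

    Follows the sklearn orientation (rows = samples/arrays, columns =
    features/genes).  ``fit`` stores the per-rank mean distribution of the
    training arrays; ``transform`` maps every row onto it by rank, ties
    averaged.  ``zonemap.quantile_normalize`` is the genes-x-samples
    functional wrapper.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.n_features_in_ = X.shape[1]
        self.reference_distribution_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_distribution_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}")
        csum = np.concatenate([[0.0], np.cumsum(self.reference_distribution_)])
        out = np.empty_like(X, dtype=float)
        for i in range(X.shape[0]):
            rmin = rankdata(X[i], method="min").astype(int)
            rmax = rankdata(X[i], method="max").astype(int)
            out[i] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
        return out
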