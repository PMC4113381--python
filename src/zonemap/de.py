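"""Spatially regulated gene calling between tissue zones.

A gene is called spatially regulated between two zones when its expression
differs by at least ``fc_threshold``-fold (default 2) with a one-way ANOVA
false discovery rate below ``q_threshold`` (default 0.05, Benjamini-
Hochberg over all genes tested in the zone pair).  Group means are taken on
the log2 scale and antilogged before the fold-change, i.e. fold-changes are
ratios of geometric means, matching how raw-signal pairs in array reports
convert to the printed fold-change column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, fold_symbol

__all__ = [
    "one_way_anova_p",
    "bh_fdr",
    "fold_change",
    "call_spatially_regulated",
    "DirectionalGeneList",
    "SpatialDECaller",
]

UP_IN_A = "up_in_a"
UP_IN_B = "up_in_b"
NONE = "none"


def one_way_anova_p(groups) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA.

    Returns ``(F, p)`` with p from the upper tail of F(k-1, N-k).  Two
    degenerate cases are resolved explicitly: all values identical gives
    ``(0, 1)``; zero residual variance with unequal group means gives
    ``(inf, 0)`` with a warning.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    means = [a.mean() for a in arrs]
    if pooled_within == 0.0:
        if np.ptp(means) == 0.0:
            return 0.0, 1.0
        warnings.warn("zero residual variance with unequal means; p reported as 0")
        return np.inf, 0.0
    f_stat, p = stats.f_oneway(*arrs)
    return float(f_stat), float(p)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean_a: float, mean_b: float) -> tuple[float, str]:
    """Linear fold-change between two positive group means, with direction.

    Returns ``(max/min, side of the larger mean)``; equal means give
    ``(1.0, "none")``.  Rounding to the nearest integer is left to report
    formatting.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("group means must be positive on the linear scale")
    if mean_a == mean_b:
        return 1.0, NONE
    if mean_a > mean_b:
        return mean_a / mean_b, UP_IN_A
    return mean_b / mean_a, UP_IN_B


@dataclass
class DirectionalGeneList:
    """Spatially regulated genes upregulated on one side of a zone pair."""

    tissue: str
    zone_pair: tuple
    up_zone: str
    genes: tuple = field(default_factory=tuple)

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


class SpatialDECaller:
    """Estimator-style wrapper around the spatial DE call for one zone pair.

    Parameters follow the calling rule: ``fc_threshold``-fold difference
    (linear scale) and BH FDR below ``q_threshold``.  After :meth:`fit` the
    results live in ``table_`` (per-gene records), ``up_in_a_`` and
    ``up_in_b_`` (directional gene lists).
    """

    def __init__(self, zone_a: str, zone_b: str, fc_threshold: float = 2.0,
                 q_threshold: float = 0.05):
        self.zone_a = zone_a
        self.zone_b = zone_b
        self.fc_threshold = fc_threshold
        self.q_threshold = q_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"zone_a": self.zone_a, "zone_b": self.zone_b,
                "fc_threshold": self.fc_threshold, "q_threshold": self.q_threshold}

    def set_params(self, **params) -> "SpatialDECaller":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, matrix: ExpressionMatrix) -> "SpatialDECaller":
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")
        a = matrix.zone_values(self.zone_a).to_numpy(dtype=float)
        b = matrix.zone_values(self.zone_b).to_numpy(dtype=float)
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError("each zone needs >= 2 replicate samples")

        mean_a_log = a.mean(axis=1)
        mean_b_log = b.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_stat, p_raw = stats.f_oneway(a, b, axis=1)
        # zero-residual-variance genes: identical values => null; unequal
        # means with no noise => maximally significant
        within = ((a - mean_a_log[:, None]) ** 2).sum(axis=1) + \
                 ((b - mean_b_log[:, None]) ** 2).sum(axis=1)
        degenerate = within == 0.0
        if degenerate.any():
            equal = degenerate & np.isclose(mean_a_log, mean_b_log)
            f_stat = np.where(equal, 0.0, f_stat)
            p_raw = np.where(equal, 1.0, p_raw)
            forced = degenerate & ~equal
            f_stat = np.where(forced, np.inf, f_stat)
            p_raw = np.where(forced, 0.0, p_raw)

        q = bh_fdr(p_raw)
        diff = mean_a_log - mean_b_log
        mean_a_lin = 2.0 ** mean_a_log
        mean_b_lin = 2.0 ** mean_b_log
        fc = 2.0 ** np.abs(diff)
        direction = np.where(diff > 0, UP_IN_A, np.where(diff < 0, UP_IN_B, NONE))
        called = (fc >= self.fc_threshold) & (q < self.q_threshold) & (direction != NONE)

        self.table_ = pd.DataFrame({
            "gene": matrix.gene_ids,
            "zone_a": self.zone_a, "zone_b": self.zone_b,
            "mean_a": mean_a_lin, "mean_b": mean_b_lin,
            "fold_change": fc, "direction": direction,
            "p_raw": p_raw, "q_fdr": q, "called": called,
        })
        tissue = str(matrix.samples["tissue"].iloc[0])
        genes = np.asarray(matrix.gene_ids, dtype=object)
        up_a = [fold_symbol(g) for g in genes[called & (direction == UP_IN_A)]]
        up_b = [fold_symbol(g) for g in genes[called & (direction == UP_IN_B)]]
        self.up_in_a_ = DirectionalGeneList(tissue, (self.zone_a, self.zone_b),
                                            self.zone_a, tuple(up_a))
        self.up_in_b_ = DirectionalGeneList(tissue, (self.zone_a, self.zone_b),
                                            self.zone_b, tuple(up_b))
        self.universe_ = frozenset(fold_symbol(g) for g in genes)
        return self


def call_spatially_regulated(matrix: ExpressionMatrix, zone_a: str, zone_b: str,
                             fc_threshold: float = 2.0, q_threshold: float = 0.05):
    """Call spatially regulated genes between two zones of one matrix.

    Returns ``(table, up_in_a, up_in_b)``: the per-gene record table and
    the two disjoint directional gene lists.
    """
    caller = SpatialDECaller(zone_a, zone_b, fc_threshold, q_threshold).fit(matrix)
    return caller.table_, caller.up_in_a_, caller.up_in_b_
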