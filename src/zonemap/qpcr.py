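"""ΔΔCT relative quantification and zone-comparison statistics for qPCR.

Relative expression of a target gene i is quantified against a housekeeping
reference (here typically 18S rRNA) as ``2^-(CT_i - CT_ref) x 10^6``; the
1e6 factor only makes the numbers convenient and cancels in every
comparison.  Zone comparisons are made on log2 relative expression with a
repeated-measures one-way ANOVA (animal as the subject factor) followed by
two-sided paired t-tests for predetermined zone pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "QpcrTable",
    "collapse_replicates",
    "relative_expression",
    "relative_expression_table",
    "zone_statistics",
]

SCALE = 1e6

REQUIRED_COLUMNS = ("animal", "zone", "gene", "replicate", "ct")


@dataclass
class QpcrTable:
    """Raw threshold-cycle measurements, one row per technical replicate."""

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"CT table missing columns: {missing}")
        if (self.data["ct"] <= 0).any() or not np.isfinite(self.data["ct"]).all():
            raise ValueError("CT values must be finite and > 0")
        genes = set(self.data["gene"])
        if self.reference_gene not in genes:
            raise ValueError(
                f"reference gene {self.reference_gene!r} not measured in the table")
        # the reference must exist for every (animal, zone) cell
        cells = set(map(tuple, self.data[["animal", "zone"]].itertuples(index=False)))
        ref = self.data[self.data["gene"] == self.reference_gene]
        ref_cells = set(map(tuple, ref[["animal", "zone"]].itertuples(index=False)))
        if cells - ref_cells:
            raise ValueError(
                f"reference gene missing for cells: {sorted(cells - ref_cells)[:5]}")

    @property
    def zones(self) -> list[str]:
        seen: dict[str, None] = {}
        for z in self.data["zone"]:
            seen.setdefault(str(z))
        return list(seen)


def collapse_replicates(table: QpcrTable) -> pd.DataFrame:
    """Mean CT over technical replicates per (animal, zone, gene).

    Returns a tidy frame with columns ``animal, zone, gene, ct, n_replicates``.
    Raises if any measured gene is missing for some (animal, zone) cell the
    experiment covers.
    """
    grouped = (table.data.groupby(["animal", "zone", "gene"], sort=True)["ct"]
               .agg(["mean", "size"]).reset_index()
               .rename(columns={"mean": "ct", "size": "n_replicates"}))
    animals = sorted(set(table.data["animal"]))
    zones = sorted(set(table.data["zone"]))
    genes = sorted(set(table.data["gene"]))
    have = set(map(tuple, grouped[["animal", "zone", "gene"]].itertuples(index=False)))
    missing = [(a, z, g) for a in animals for z in zones for g in genes
               if (a, z, g) not in have]
    if missing:
        raise ValueError(f"missing CT measurements for: {missing[:5]}")
    return grouped


def relative_expression(ct_gene, ct_ref):
    """ΔΔCT relative expression: ``2^-(ct_gene - ct_ref) x 10^6``."""
    return 2.0 ** -(np.asarray(ct_gene, dtype=float) - np.asarray(ct_ref, dtype=float)) * SCALE


def relative_expression_table(table: QpcrTable) -> pd.DataFrame:
    """Per-(animal, zone, gene) relative expression versus the reference.

    Technical replicates are collapsed to a mean CT first; the reference
    gene itself is dropped from the output (its relative expression is 1e6
    by construction).
    """
    collapsed = collapse_replicates(table)
    ref = (collapsed[collapsed["gene"] == table.reference_gene]
           .set_index(["animal", "zone"])["ct"])
    out = collapsed[collapsed["gene"] != table.reference_gene].copy()
    ref_ct = ref.loc[list(map(tuple, out[["animal", "zone"]].itertuples(index=False)))]
    out["relative_expression"] = relative_expression(out["ct"].to_numpy(),
                                                     ref_ct.to_numpy())
    return out[["animal", "zone", "gene", "relative_expression"]]


def _rm_anova_p(frame: pd.DataFrame) -> tuple[float, float]:
    """Repeated-measures one-way ANOVA (zone within animal) on log2 values."""
    values = frame.pivot(index="animal", columns="zone", values="log2_rel")
    arr = values.to_numpy()
    if np.allclose(arr - arr.mean(axis=1, keepdims=True), 0.0):
        return 0.0, 1.0  # no within-animal zone variation at all
    fit = AnovaRM(frame, depvar="log2_rel", subject="animal",
                  within=["zone"]).fit()
    row = fit.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])


def zone_statistics(records: pd.DataFrame, comparisons: list,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Zone-difference statistics per gene on log2 relative expression.

    ``records`` is the output of :func:`relative_expression_table`;
    ``comparisons`` lists the predetermined zone pairs, e.g.
    ``[("SZ", "IDZ"), ("RZ", "PZ")]``.  For each gene the repeated-measures
    ANOVA p (omnibus zone effect) is reported alongside a two-sided paired
    t-test per pair; every animal must be measured in every compared zone.
    """
    req = {"animal", "zone", "gene", "relative_expression"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    records = records.copy()
    records["log2_rel"] = np.log2(records["relative_expression"])
    animals = sorted(set(records["animal"]))
    if len(animals) < 2:
        raise ValueError("need at least 2 animals for paired statistics")
    zones = set(records["zone"].astype(str))
    for za, zb in comparisons:
        if za not in zones or zb not in zones:
            raise ValueError(f"comparison ({za}, {zb}) names an unmeasured zone")

    rows = []
    for gene, frame in records.groupby("gene", sort=True):
        cells = frame.groupby(["animal", "zone"]).size()
        missing = [(a, z) for a in animals for z in sorted(zones)
                   if (a, z) not in cells.index]
        if missing:
            raise ValueError(f"gene {gene!r}: unbalanced design, missing {missing[:5]}")
        f_stat, p_anova = _rm_anova_p(frame[["animal", "zone", "log2_rel"]])
        wide = frame.pivot(index="animal", columns="zone", values="log2_rel")
        for za, zb in comparisons:
            d = (wide[za] - wide[zb]).to_numpy()
            if np.isclose(d.std(ddof=1), 0.0):
                # degenerate pairing: identical differences in every animal
                t_stat = 0.0 if np.isclose(d.mean(), 0.0) else np.inf * np.sign(d.mean())
                p_t = 1.0 if t_stat == 0.0 else 0.0
            else:
                t_stat, p_t = stats.ttest_rel(wide[za], wide[zb])
            diff = float(d.mean())
            rows.append({
                "gene": gene, "zone_a": za, "zone_b": zb,
                "anova_F": f_stat, "anova_p": p_anova,
                "mean_log2_diff": diff, "fold_change": float(2.0 ** diff),
                "t": float(t_stat), "p_paired": float(p_t),
                "significant": bool(p_anova < alpha and p_t < alpha),
            })
    return pd.DataFrame(rows)
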