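"""Core in-memory containers for zonal expression analysis.

An :class:`ExpressionMatrix` bundles a log2 genes-by-samples matrix with the
sample annotations (tissue, zone, replicate) that every downstream stage
needs, plus a platform label used when intersecting gene universes across
experiments.  Gene identity is case-insensitive throughout the package:
microarray annotations for the same symbol vary in casing between platforms,
so ``Prg4`` and ``PRG4`` name the same gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ("sample_id", "tissue", "zone", "replicate")


def fold_symbol(symbol: str) -> str:
    """Canonical (case-folded) form of a gene symbol."""
    return str(symbol).strip().casefold()


@dataclass
class ExpressionMatrix:
    """Log2 expression values for genes x samples with zonal annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample id,
        holding log2 intensities.
    samples
        DataFrame with columns ``sample_id, tissue, zone, replicate``; one
        row per column of ``values``, in the same order.
    platform
        Free-text label for the measurement platform; used to tell the two
        simulated/loaded experiments apart when building a shared universe.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    platform: str = "platform"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a DataFrame (genes x samples)")
        self.samples = pd.DataFrame(self.samples).reset_index(drop=True)
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        sheet_ids = list(self.samples["sample_id"].astype(str))
        col_ids = list(map(str, self.values.columns))
        if sheet_ids != col_ids:
            extra = sorted(set(col_ids) - set(sheet_ids))
            if extra:
                raise ValueError(f"samples missing from sample sheet: {extra}")
            # same set, different order: align the sheet to the matrix
            self.samples = (
                self.samples.set_index("sample_id").loc[col_ids].reset_index()
            )
        if self.samples["sample_id"].duplicated().any():
            dups = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        folded = self.values.index.map(fold_symbol)
        if folded.duplicated().any():
            dups = sorted(set(folded[folded.duplicated()]))
            raise ValueError(
                f"duplicate gene symbols after case folding: {dups[:5]}"
                " (collapse duplicates before constructing the matrix)"
            )
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")

    # -- convenience accessors -------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(map(str, self.values.index))

    @property
    def gene_universe(self) -> set[str]:
        """Case-folded set of genes on this platform."""
        return {fold_symbol(g) for g in self.values.index}

    @property
    def zones(self) -> list[str]:
        """Zone labels in first-appearance (design) order."""
        seen: dict[str, None] = {}
        for z in self.samples["zone"]:
            seen.setdefault(str(z))
        return list(seen)

    def zone_samples(self, zone: str) -> list[str]:
        mask = self.samples["zone"].astype(str) == str(zone)
        if not mask.any():
            raise KeyError(f"unknown zone {zone!r}; have {self.zones}")
        return list(self.samples.loc[mask, "sample_id"].astype(str))

    def zone_values(self, zone: str) -> pd.DataFrame:
        """Log2 values of all genes restricted to one zone's samples."""
        return self.values[self.zone_samples(zone)]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        wanted = {fold_symbol(g) for g in genes}
        keep = [g for g in self.values.index if fold_symbol(g) in wanted]
        return ExpressionMatrix(self.values.loc[keep], self.samples.copy(), self.platform)


@dataclass(frozen=True)
class MarkerSet:
    """A named zonal marker gene list (symbols stored case-folded)."""

    name: str
    zone: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        folded = frozenset(fold_symbol(g) for g in self.genes)
        object.__setattr__(self, "genes", folded)
        if not self.genes:
            raise ValueError(f"marker set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def restrict(self, universe) -> frozenset:
        """Markers present in a (case-folded) gene universe."""
        uni = {fold_symbol(g) for g in universe}
        return frozenset(g for g in self.genes if g in uni)
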