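"""On-disk formats: expression TSV, sample sheets, marker lists, result tables.

Expression matrices use a plain TSV dialect: first column ``gene``, one
column per sample id, tab-separated, ``#``-prefixed comment lines ignored.
Sample sheets are CSV or TSV with columns ``sample_id, tissue, zone,
replicate``.  Marker lists are two-column (zone, gene) TSV.  Result tables
are written with a header, floats at 6 significant digits, NaN as ``NA``,
in deterministic row order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MarkerSet, fold_symbol

__all__ = [
    "read_expression",
    "write_expression",
    "read_marker_sets",
    "write_marker_sets",
    "write_table",
    "read_table",
    "collapse_duplicate_genes",
]


def _read_sample_sheet(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    sheet = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    missing = [c for c in ("sample_id", "tissue", "zone", "replicate")
               if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {missing}")
    return sheet


def collapse_duplicate_genes(values: pd.DataFrame,
                             p_values: pd.Series | None = None) -> pd.DataFrame:
    """Collapse rows sharing a case-folded symbol to a single row.

    With DE context (``p_values`` indexed like ``values``) the row with the
    smallest p wins; otherwise the row with the highest mean expression.
    The surviving row keeps its original symbol spelling.
    """
    folded = values.index.map(fold_symbol)
    if not folded.duplicated().any():
        return values
    if p_values is not None:
        score = -pd.Series(np.asarray(p_values, dtype=float), index=values.index)
    else:
        score = values.mean(axis=1)
    keep_rows = []
    best: dict[str, tuple] = {}
    for pos, (sym, s) in enumerate(zip(folded, score)):
        if sym not in best or s > best[sym][0]:
            best[sym] = (s, pos)
    keep_positions = sorted(pos for _s, pos in best.values())
    keep_rows = values.index[keep_positions]
    return values.loc[keep_rows]


def read_expression(matrix_path, sample_sheet_path,
                    platform: str = "platform") -> ExpressionMatrix:
    """Read an expression TSV plus its sample sheet into an ExpressionMatrix.

    Every matrix column must be described in the sample sheet (a missing
    sample is a hard error naming it); non-numeric cells raise with their
    row and column coordinates.  Duplicate symbols are collapsed to the
    highest-mean row.
    """
    matrix_path = Path(matrix_path)
    raw = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0, dtype=str)
    values = pd.DataFrame(index=raw.index.astype(str))
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.argmax()]
            raise ValueError(
                f"non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, "
                f"sample {col!r} in {matrix_path}")
        if converted.isna().any():
            gene = raw.index[converted.isna().argmax()]
            raise ValueError(f"missing value at gene {gene!r}, sample {col!r}")
        values[str(col)] = converted.to_numpy(dtype=float)

    sheet = _read_sample_sheet(sample_sheet_path)
    known = set(sheet["sample_id"].astype(str))
    orphans = [c for c in values.columns if c not in known]
    if orphans:
        raise ValueError(
            f"sample sheet has no metadata for sample(s): {orphans}")
    sheet = sheet.set_index("sample_id").loc[list(values.columns)].reset_index()
    values = collapse_duplicate_genes(values)
    return ExpressionMatrix(values, sheet, platform=platform)


def write_expression(matrix: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    """Write the expression TSV and its sample sheet."""
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t", float_format="%.10g")
    sep = "," if str(sample_sheet_path).lower().endswith(".csv") else "\t"
    matrix.samples.to_csv(sample_sheet_path, sep=sep, index=False)


def read_marker_sets(path) -> list[MarkerSet]:
    """Read a two-column (zone, gene) TSV into one MarkerSet per zone.

    Zone labels are kept verbatim (sets are label-agnostic); genes are
    de-duplicated case-insensitively within a zone.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"marker list {path} needs two columns (zone, gene)")
    if table.empty:
        raise ValueError(f"marker list {path} is empty")
    zone_col, gene_col = table.columns[:2]
    sets = []
    for zone, group in table.groupby(zone_col, sort=True):
        genes = frozenset(fold_symbol(g) for g in group[gene_col].dropna())
        sets.append(MarkerSet(name=f"{zone}_markers", zone=str(zone), genes=genes))
    return sets


def write_marker_sets(marker_sets, path) -> None:
    rows = [{"zone": ms.zone, "gene": g}
            for ms in marker_sets for g in sorted(ms.genes)]
    pd.DataFrame(rows, columns=["zone", "gene"]).to_csv(path, sep="\t", index=False)


def write_table(records, path) -> None:
    """Write records (DataFrame or list of dicts) as a deterministic TSV.

    Header always present; floats rendered with 6 significant digits; NaN
    serialized as ``NA``.  An empty record list with no schema yields a
    header-only file when given a DataFrame.
    """
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
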