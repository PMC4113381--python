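"""Cross-platform gene-list overlap inference.

Two zonal experiments run on different platforms cannot be compared by
expression level directly, but their directional spatially-regulated gene
lists can be compared by membership.  Over the universe of genes shared by
both platforms (and tested in both analyses), the observed overlap k of two
lists of sizes n_a and n_b is set against the independence expectation
``n_a * n_b / N`` with a Pearson chi-square test on the 2x2 membership
table (no continuity correction, df = 1).  Families of such comparisons —
canonically the 12 articular-direction x growth-plate-directional-list
combinations — are corrected with the Holm-Sidak step-down method, and an
overlap is labelled more/less than expected by chance only when the
adjusted p clears alpha.  Marker-set localization reuses the same test
against a zone's known marker genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MarkerSet, fold_symbol

__all__ = [
    "OverlapResult",
    "MarkerLocalization",
    "intersect_universe",
    "directional_overlap_test",
    "holm_sidak_adjust",
    "all_pairs_correspondence",
    "marker_localization",
]

MORE = "more_than_chance"
LESS = "less_than_chance"
NONE = "none"


@dataclass(frozen=True)
class OverlapResult:
    """Chi-square assessment of one gene-list overlap against chance."""

    list_a_id: str
    list_b_id: str
    N: int
    n_a: int
    n_b: int
    k: int
    expected: float
    chi2: float
    p_raw: float
    p_adj: float
    direction: str
    degenerate: bool = False

    def as_record(self) -> dict:
        return {
            "list_a": self.list_a_id, "list_b": self.list_b_id,
            "N": self.N, "n_a": self.n_a, "n_b": self.n_b, "k": self.k,
            "expected": self.expected, "chi2": self.chi2,
            "p_raw": self.p_raw, "p_adj": self.p_adj,
            "direction": self.direction, "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class MarkerLocalization:
    """How many of a zone's markers land in one directional list."""

    marker_set: str
    marker_zone: str
    direction_list: str
    K: int
    k_up: int
    overlap: OverlapResult


def intersect_universe(genes_a, genes_b) -> list[str]:
    """Case-insensitive intersection of two gene universes, sorted."""
    folded_a = {fold_symbol(g) for g in genes_a}
    folded_b = {fold_symbol(g) for g in genes_b}
    return sorted(folded_a & folded_b)


def _pearson_chi2_2x2(k: int, n_a: int, n_b: int, N: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on the
    membership table ``[[k, n_a-k], [n_b-k, N-n_a-n_b+k]]``."""
    observed = np.array([k, n_a - k, n_b - k, N - n_a - n_b + k], dtype=float)
    row = np.array([n_a, N - n_a], dtype=float)
    col = np.array([n_b, N - n_b], dtype=float)
    expected = np.array([row[0] * col[0], row[0] * col[1],
                         row[1] * col[0], row[1] * col[1]]) / N
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def directional_overlap_test(list_a, list_b, universe, alpha: float = 0.05,
                             list_a_id: str = "list_a",
                             list_b_id: str = "list_b") -> OverlapResult:
    """Test one pair of gene lists for more/less overlap than chance.

    Lists are restricted (case-insensitively) to the universe before
    counting.  A zero margin (either list empty or covering the whole
    universe) makes the chi-square undefined; the result is then flagged
    degenerate with ``p = NaN``.  Direction is assigned from the sign of
    ``k - expected`` when the (possibly adjusted) p clears ``alpha``; the
    constructor fills ``p_adj = p_raw`` so single tests are interpretable
    before family correction.
    """
    uni = {fold_symbol(g) for g in universe}
    N = len(uni)
    if N < 1:
        raise ValueError("empty gene universe")
    set_a = {fold_symbol(g) for g in list_a} & uni
    set_b = {fold_symbol(g) for g in list_b} & uni
    n_a, n_b, k = len(set_a), len(set_b), len(set_a & set_b)
    expected = n_a * n_b / N
    if n_a in (0, N) or n_b in (0, N):
        return OverlapResult(list_a_id, list_b_id, N, n_a, n_b, k, expected,
                             np.nan, np.nan, np.nan, NONE, degenerate=True)
    chi2, p = _pearson_chi2_2x2(k, n_a, n_b, N)
    direction = _direction(k, expected, p, alpha)
    return OverlapResult(list_a_id, list_b_id, N, n_a, n_b, k, expected,
                         chi2, p, p, direction)


def _direction(k: float, expected: float, p_adj: float, alpha: float) -> str:
    if not np.isfinite(p_adj) or p_adj >= alpha or k == expected:
        return NONE
    return MORE if k > expected else LESS


def holm_sidak_adjust(p) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, returned in input order.

    In sorted order ``adj_(i) = 1 - (1 - p_(i))^(m - i + 1)`` with
    monotonicity enforced downward and capping at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # p = 1 hits log1p(-1) internally
        return multipletests(p, method="holm-sidak")[1]


def adjust_family(results: list, alpha: float = 0.05,
                  method: str = "holm-sidak") -> list:
    """Apply a familywise correction across a list of OverlapResults.

    Degenerate results keep ``p_adj = NaN`` and do not count toward the
    family size.  Directions are re-assigned from the adjusted p.
    """
    idx = [i for i, r in enumerate(results) if not r.degenerate]
    if idx:
        raw = [results[i].p_raw for i in idx]
        if method == "holm-sidak":
            adj = holm_sidak_adjust(raw)
        elif method == "none":
            adj = np.asarray(raw, dtype=float)
        else:
            adj = multipletests(raw, method=method)[1]
    out = list(results)
    for pos, i in enumerate(idx):
        r = results[i]
        p_adj = float(adj[pos])
        out[i] = replace(r, p_adj=p_adj,
                         direction=_direction(r.k, r.expected, p_adj, alpha))
    return out


def all_pairs_correspondence(lists_a, lists_b, universe, alpha: float = 0.05,
                             family_correction: bool = True) -> list:
    """All-pairs directional overlap tests between two tissues' lists.

    ``lists_a`` and ``lists_b`` are DirectionalGeneLists (canonically 2
    from the articular zone pair and 6 from the three growth-plate zone
    pairs, giving the 12-comparison family).  Holm-Sidak is applied across
    the full family of non-degenerate raw p-values.
    """
    results = []
    for la in lists_a:
        for lb in lists_b:
            results.append(directional_overlap_test(
                la.gene_set, lb.gene_set, universe, alpha=alpha,
                list_a_id=_list_id(la), list_b_id=_list_id(lb)))
    if family_correction:
        results = adjust_family(results, alpha=alpha, method="holm-sidak")
    return results


def _list_id(lst) -> str:
    za, zb = lst.zone_pair
    return f"{lst.tissue}:{lst.up_zone}>({za}-{zb})"


def marker_localization(marker_set: MarkerSet, directional_lists, universe,
                        alpha: float = 0.05) -> list:
    """Locate a zonal marker set within each directional gene list.

    For every list, reports how many of the K markers present in the
    universe fall in the list (k_up of K) together with the chi-square
    overlap assessment.  Marker localizations are tested individually
    (no family correction) by default.
    """
    markers = marker_set.restrict(universe)
    if not markers:
        raise ValueError(
            f"marker set {marker_set.name!r} has no genes in the universe")
    out = []
    for lst in directional_lists:
        res = directional_overlap_test(
            markers, lst.gene_set, universe, alpha=alpha,
            list_a_id=f"markers:{marker_set.name}", list_b_id=_list_id(lst))
        out.append(MarkerLocalization(
            marker_set.name, marker_set.zone, _list_id(lst),
            K=len(markers), k_up=res.k, overlap=res))
    return out


def results_table(results) -> pd.DataFrame:
    """OverlapResults (or MarkerLocalizations) as a tidy DataFrame."""
    records = []
    for r in results:
        if isinstance(r, MarkerLocalization):
            rec = r.overlap.as_record()
            rec.update({"marker_set": r.marker_set, "K": r.K, "k_up": r.k_up})
        else:
            rec = r.as_record()
        records.append(rec)
    return pd.DataFrame(records)
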