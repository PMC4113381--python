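"""Self-benchmarks: parameter recovery of the pipeline on planted truth.

These routines run the full method against the synthetic generator under
the study conditions the package emulates (n = 4 replicates per zone,
sigma = 0.35 log2 units of replicate noise, planted effects of at least
2.5-fold) and report recovery statistics: recall and empirical FDR of the
spatial DE caller, recovery of planted cross-tissue correspondences, the
familywise type-I error of the overlap family under the independence null,
and power of the qPCR zone statistics on a strongly zone-specific gene.
"""

from __future__ import annotations

import numpy as np

from .correspond import all_pairs_correspondence, intersect_universe
from .de import call_spatially_regulated
from .qpcr import relative_expression_table, zone_statistics
from .simulate import (SimulationDesign, ZoneProgram, default_study_design,
                       simulate_dataset, simulate_qpcr, simulate_tissue_pair)

__all__ = [
    "de_recovery",
    "correspondence_recovery",
    "familywise_type1",
    "qpcr_power",
]


def de_recovery(seed: int, n_genes: int = 10000, n_planted: int = 500,
                sigma: float = 0.35, n_replicates: int = 4) -> dict:
    """Recall and empirical FDR of the spatial DE call on planted genes.

    Plants ``n_planted`` genes (half up in each zone) with >= 2.5-fold
    effects among ``n_genes`` total and scores the >= 2-fold / FDR < 0.05
    call against the truth.
    """
    half = n_planted // 2
    programs = [ZoneProgram("up_a", "T", {"A": 1.0}, size=half),
                ZoneProgram("up_b", "T", {"B": 1.0}, size=n_planted - half)]
    design = SimulationDesign(tissues=[("T", ("A", "B"))], n_genes=n_genes,
                              n_replicates=n_replicates, sigma=sigma,
                              programs=programs, seed=seed)
    matrix, truth = simulate_dataset(design, "T")
    _, up_a, up_b = call_spatially_regulated(matrix, "A", "B")
    called = up_a.gene_set | up_b.gene_set
    planted = truth.planted_for("T", "A", "B", "A") | \
        truth.planted_for("T", "A", "B", "B")
    recall = len(called & planted) / len(planted)
    fdr = len(called - planted) / max(len(called), 1)
    return {"recall": recall, "empirical_fdr": fdr, "n_called": len(called),
            "n_planted": len(planted), "n_genes": n_genes}


def _study_overlaps(seed: int, rho: float, n_genes: int, program_size: int,
                    platform_overlap: float = 1.0, alpha: float = 0.05):
    design = default_study_design(seed=seed, n_genes=n_genes,
                                  program_size=program_size, rho=rho,
                                  platform_overlap=platform_overlap)
    mat_a, mat_b, truth = simulate_tissue_pair(design)
    lists_a, lists_b = [], []
    for m, store in ((mat_a, lists_a), (mat_b, lists_b)):
        for za, zb in design.zone_pairs(m.platform):
            _, ua, ub = call_spatially_regulated(m, za, zb)
            store += [ua, ub]
    universe = intersect_universe(mat_a.gene_universe, mat_b.gene_universe)
    results = all_pairs_correspondence(lists_a, lists_b, universe, alpha=alpha)
    return results, truth


def correspondence_recovery(seed: int, rho: float = 0.8, n_genes: int = 1000,
                            program_size: int = 100,
                            platform_overlap: float = 0.8) -> dict:
    """Fraction of planted cross-tissue correspondences flagged enriched."""
    results, truth = _study_overlaps(seed, rho, n_genes, program_size,
                                     platform_overlap)
    by_id = {(r.list_a_id, r.list_b_id): r for r in results}
    planted_keys = []
    for ka, kb in truth.shared_pairs:
        ta, (za, zb), ua = ka
        tb, (zc, zd), ub = kb
        planted_keys.append((f"{ta}:{ua}>({za}-{zb})", f"{tb}:{ub}>({zc}-{zd})"))
    hits = sum(by_id[k].direction == "more_than_chance" for k in planted_keys)
    n_sig = sum(r.direction != "none" for r in results)
    return {"recovery_rate": hits / max(len(planted_keys), 1),
            "n_planted_pairs": len(planted_keys),
            "n_significant": n_sig, "n_comparisons": len(results)}


def familywise_type1(seed: int, n_replicates: int = 500, n_genes: int = 1000,
                     program_size: int = 100, alpha: float = 0.05) -> dict:
    """Familywise false-positive rate of the 12-comparison overlap family.

    Under rho = 0 the two tissues' programs are independent draws, so any
    more/less-than-chance call after Holm-Sidak is a familywise false
    positive.  Expected overlaps are ~program_size^2 / n_genes = 10 at the
    defaults, large enough for the chi-square approximation.
    """
    rng = np.random.default_rng([seed, 0x7471])
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    false_families = 0
    for s in sub_seeds:
        results, _ = _study_overlaps(int(s), rho=0.0, n_genes=n_genes,
                                     program_size=program_size, alpha=alpha)
        if any(r.direction != "none" for r in results):
            false_families += 1
    return {"type1_rate": false_families / n_replicates,
            "n_replicates": n_replicates, "alpha": alpha}


def qpcr_power(seed: int, fold: float = 200.0, noise_sd: float = 0.3,
               n_animals: int = 4) -> dict:
    """Paired-test power for a strongly zone-specific validation gene.

    Plants a ``fold``-times-higher SZ expression (the magnitude reported
    for the canonical superficial-zone marker) and checks every SZ-vs-other
    paired comparison.
    """
    zones = ["SZ", "IDZ", "RZ", "PZ", "HZ"]
    profile = {"18S": {z: 0.0 for z in zones},
               "marker": {z: (np.log2(fold) if z == "SZ" else 0.0)
                          for z in zones}}
    table = simulate_qpcr(profile, n_animals=n_animals, noise_sd=noise_sd,
                          seed=seed)
    records = relative_expression_table(table)
    out = zone_statistics(records, [("SZ", z) for z in zones[1:]])
    gene = out[out["gene"] == "marker"]
    return {"min_fold": float(gene["fold_change"].min()),
            "max_p_paired": float(gene["p_paired"].max()),
            "all_significant": bool((gene["p_paired"] < 0.05).all()),
            "n_comparisons": len(gene)}
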