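"""Config-driven orchestration of the full zonal correspondence analysis.

A run takes either a simulation design or on-disk expression matrices for
two tissues, then executes: per-tissue spatial DE over every zone pair,
cross-platform universe intersection, the all-pairs directional overlap
family with Holm-Sidak correction, optional marker-set localization,
sample-structure summaries (PCA, clustering, z-matrix), and optional qPCR
zone statistics.  Every artifact is written to the output directory along
with a deterministic JSON manifest recording parameters, seed, and stage
status.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import ExpressionMatrix
from .correspond import (all_pairs_correspondence, intersect_universe,
                         marker_localization, results_table)
from .de import call_spatially_regulated
from .io import (read_expression, read_marker_sets, write_expression,
                 write_table)
from .qpcr import QpcrTable, relative_expression_table, zone_statistics
from .simulate import default_study_design, simulate_qpcr, simulate_tissue_pair
from .structure import cluster_samples, pca_samples, zscore_matrix

import pandas as pd

logger = logging.getLogger("zonemap")

__all__ = ["PipelineConfig", "ValidationError", "run_pipeline"]


class ValidationError(ValueError):
    """Configuration problem detected before any computation."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs.

    Either ``simulation`` (kwargs for :func:`default_study_design`) or
    ``inputs`` (two tissue entries with matrix/sample-sheet paths and
    ordered zone lists) must be provided.
    """

    outdir: str = "zonemap_out"
    seed: int = 0
    fc_threshold: float = 2.0
    q_threshold: float = 0.05
    alpha: float = 0.05
    family_correction: bool = True
    metric: str = "euclidean"
    linkage: str = "average"
    pca_standardize: bool = False
    simulation: dict | None = None
    inputs: list | None = None          # [{tissue, zones, matrix, sample_sheet}, ...]
    markers: str | None = None          # marker list TSV
    markers_from_truth: int = 0         # simulate mode: markers per zone program
    qpcr: dict | None = None            # {ct_table, reference_gene, comparisons}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.fc_threshold < 1 or self.q_threshold <= 0 or self.alpha <= 0:
            raise ValidationError("thresholds must be positive (fc_threshold >= 1)")
        if (self.simulation is None) == (self.inputs is None):
            raise ValidationError("provide exactly one of 'simulation' or 'inputs'")
        if self.inputs is not None:
            if len(self.inputs) != 2:
                raise ValidationError("need exactly two tissue inputs")
            for entry in self.inputs:
                for key in ("tissue", "zones", "matrix", "sample_sheet"):
                    if key not in entry:
                        raise ValidationError(f"tissue input missing key {key!r}")
                zones = entry["zones"]
                if len(set(zones)) != len(zones) or len(zones) < 2:
                    raise ValidationError(
                        f"tissue {entry['tissue']!r}: zones must be >= 2 and unique")
        if self.qpcr is not None and "comparisons" in self.qpcr:
            for pair in self.qpcr["comparisons"]:
                if len(pair) != 2:
                    raise ValidationError(f"bad qPCR comparison {pair!r}")


def _zone_pairs(zones) -> list:
    import itertools
    return list(itertools.combinations(zones, 2))


def _acquire(config: PipelineConfig):
    """Matrices + zone orders (+ truth and design in simulation mode)."""
    if config.simulation is not None:
        design = default_study_design(seed=config.seed, **config.simulation)
        mat_a, mat_b, truth = simulate_tissue_pair(design)
        zones = {t: list(z) for t, z in design.tissues}
        return [mat_a, mat_b], zones, truth, design
    matrices, zones = [], {}
    for entry in config.inputs:
        m = read_expression(entry["matrix"], entry["sample_sheet"],
                            platform=entry["tissue"])
        declared = [str(z) for z in entry["zones"]]
        present = set(m.zones)
        bad = [z for z in declared if z not in present]
        if bad:
            raise ValidationError(
                f"tissue {entry['tissue']!r}: declared zones {bad} not in data "
                f"(have {sorted(present)})")
        matrices.append(m)
        zones[entry["tissue"]] = declared
    return matrices, zones, None, None


def _marker_sets(config, truth, outdir):
    if config.markers:
        return read_marker_sets(config.markers)
    if config.markers_from_truth and truth is not None:
        # derive marker lists from the growth-plate-like tissue's planted
        # programs: the first markers_from_truth genes per directional set
        from .containers import MarkerSet
        sets = []
        seen_zone = set()
        for (tissue, _pair, up_zone), genes in sorted(
                truth.planted.items(), key=lambda kv: str(kv[0])):
            if tissue == truth_second_tissue(truth) and up_zone not in seen_zone and genes:
                chosen = sorted(genes)[: config.markers_from_truth]
                sets.append(MarkerSet(f"{up_zone}_markers", up_zone, frozenset(chosen)))
                seen_zone.add(up_zone)
        return sets
    return []


def truth_second_tissue(truth) -> str:
    tissues = sorted({k[0] for k in truth.planted})
    return tissues[-1]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory.

    Any stage error aborts with a stage-named message; partial outputs are
    retained next to a ``FAILED`` marker file.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest = {
        "zonemap_version": __version__,
        "seed": config.seed,
        "parameters": {
            "fc_threshold": config.fc_threshold,
            "q_threshold": config.q_threshold,
            "alpha": config.alpha,
            "family_correction": config.family_correction,
            "metric": config.metric,
            "linkage": config.linkage,
            "pca_standardize": config.pca_standardize,
        },
        "stages": {},
        "outputs": [],
    }

    def emit(name, writer):
        path = outdir / name
        writer(path)
        manifest["outputs"].append(name)
        return path

    stage = "acquire"
    try:
        matrices, zones, truth, design = _acquire(config)
        logger.info("acquire: %d tissues, %s",
                    len(matrices), {t: len(z) for t, z in zones.items()})
        for m in matrices:
            emit(f"expression_{m.platform}.tsv",
                 lambda p, m=m: write_expression(m, p, str(p).replace(".tsv", "_samples.tsv")))
        if truth is not None:
            emit("truth.json", lambda p: Path(p).write_text(
                json.dumps(truth.to_json_dict(), indent=1, sort_keys=True)))
        manifest["stages"][stage] = "ok"

        stage = "spatial_de"
        lists_by_tissue = {}
        tested_universe = {}
        de_tables = {}
        for m in matrices:
            tissue = m.platform
            lists_by_tissue[tissue] = []
            tested_universe[tissue] = m.gene_universe
            for za, zb in _zone_pairs(zones[tissue]):
                table, up_a, up_b = call_spatially_regulated(
                    m, za, zb, config.fc_threshold, config.q_threshold)
                de_tables[(tissue, za, zb)] = table
                lists_by_tissue[tissue] += [up_a, up_b]
                emit(f"de_{tissue}_{za}_vs_{zb}.tsv",
                     lambda p, t=table: write_table(t, p))
                pair_lists = pd.DataFrame(
                    [{"gene": g, "direction": f"up_in_{za}"} for g in up_a.genes]
                    + [{"gene": g, "direction": f"up_in_{zb}"} for g in up_b.genes])
                emit(f"directional_{tissue}_{za}_vs_{zb}.tsv",
                     lambda p, t=pair_lists: write_table(t, p))
                logger.info("spatial_de: %s %s vs %s -> %d + %d called",
                            tissue, za, zb, len(up_a), len(up_b))
        manifest["stages"][stage] = "ok"

        stage = "correspondence"
        (tissue_a, tissue_b) = [m.platform for m in matrices]
        universe = intersect_universe(tested_universe[tissue_a],
                                      tested_universe[tissue_b])
        manifest["universe_size"] = len(universe)
        results = all_pairs_correspondence(
            lists_by_tissue[tissue_a], lists_by_tissue[tissue_b], universe,
            alpha=config.alpha, family_correction=config.family_correction)
        emit("overlap_results.tsv", lambda p: write_table(results_table(results), p))
        n_sig = sum(r.direction != "none" for r in results)
        logger.info("correspondence: %d comparisons over N=%d, %d significant",
                    len(results), len(universe), n_sig)
        manifest["stages"][stage] = "ok"

        stage = "markers"
        marker_sets = _marker_sets(config, truth, outdir)
        if marker_sets:
            locs = []
            for ms in marker_sets:
                locs += marker_localization(ms, lists_by_tissue[tissue_a],
                                            universe, alpha=config.alpha)
            emit("marker_localization.tsv",
                 lambda p: write_table(results_table(locs), p))
            logger.info("markers: %d sets localized", len(marker_sets))
            manifest["stages"][stage] = "ok"
        else:
            logger.info("markers: no marker sets supplied, skipped")
            manifest["stages"][stage] = "skipped"

        stage = "structure"
        first = matrices[0]
        pca = pca_samples(first, standardize=config.pca_standardize)
        emit("pca_scores.tsv", lambda p: write_table(
            pca.scores.reset_index().rename(columns={"index": "sample_id"}), p))
        emit("pca_explained.tsv", lambda p: write_table(
            pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(pca.explained_fraction))],
                          "fraction": pca.explained_fraction}), p))
        za, zb = _zone_pairs(zones[tissue_a])[0]
        de_genes = de_tables[(tissue_a, za, zb)].query("called")["gene"].tolist()
        if len(de_genes) >= 2:
            dendro = cluster_samples(first, de_genes, metric=config.metric,
                                     linkage=config.linkage)
            emit("dendrogram.json", lambda p: Path(p).write_text(
                json.dumps(dendro.to_tree_dict(), sort_keys=True)))
            z, _const = zscore_matrix(first, de_genes)
            emit("zscore_matrix.tsv", lambda p: z.reset_index(names="gene")
                 .pipe(write_table, p))
        logger.info("structure: PCA top-3 fraction %.3f, %d DE genes clustered",
                    pca.retained(3), len(de_genes))
        manifest["stages"][stage] = "ok"

        stage = "qpcr"
        if config.qpcr:
            table = pd.read_csv(config.qpcr["ct_table"])
            qt = QpcrTable(table, reference_gene=config.qpcr.get("reference_gene", "18S"))
            records = relative_expression_table(qt)
            comparisons = [tuple(p) for p in config.qpcr.get(
                "comparisons", _zone_pairs(qt.zones))]
            statsfr = zone_statistics(records, comparisons, alpha=config.alpha)
            emit("qpcr_statistics.tsv", lambda p: write_table(statsfr, p))
            logger.info("qpcr: %d genes, %d comparisons",
                        statsfr["gene"].nunique(), len(comparisons))
            manifest["stages"][stage] = "ok"
        else:
            logger.info("qpcr: no CT data supplied, skipped")
            manifest["stages"][stage] = "skipped"

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        logger.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = sorted(manifest["outputs"])
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    logger.info("done: %d artifacts in %s", len(manifest["outputs"]), outdir)
    logger.removeHandler(handler)
    handler.close()
    return outdir
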