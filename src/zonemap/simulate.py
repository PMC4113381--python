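"""Seeded, truth-annotated simulation of zonal expression experiments.

The generator emulates the statistical structure of a layered-tissue
microarray study: each tissue is sampled in a fixed number of ordered zones
with ``n_replicates`` biological replicates per zone, expression lives on a
log2 scale with per-gene baselines in the typical array-intensity range, and
"zone programs" plant log2 effects for chosen gene sets in chosen zones on
top of Gaussian replicate noise.  Two tissues can be simulated on partially
overlapping gene universes (two platforms) with a controlled fraction of
deliberately shared program genes, which is the ground truth the
cross-platform overlap inference is benchmarked against.

Everything is driven by one integer seed; per-tissue and per-stage
substreams are derived from it with CRC32 label hashing so multi-matrix
outputs are individually reproducible.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, fold_symbol
from .normalize import ProbeMatrix
from .qpcr import QpcrTable

__all__ = [
    "ZoneProgram",
    "SimulationDesign",
    "SyntheticTruth",
    "simulate_dataset",
    "simulate_tissue_pair",
    "simulate_qpcr",
    "simulate_probe_matrix",
    "default_study_design",
]


def _substream(seed: int, *labels: str) -> np.random.Generator:
    """Child RNG derived from the global seed and string labels."""
    entropy = [int(seed)] + [zlib.crc32(str(x).encode()) for x in labels]
    return np.random.default_rng(entropy)


@dataclass
class ZoneProgram:
    """A coexpression program: a gene set with a per-zone log2 effect profile.

    ``effects`` gives the zone profile in log2 units; each member gene g
    realizes the profile scaled by a per-gene amplitude drawn from the
    design's ``amplitude_range`` (so a profile of 1.0 with amplitudes in
    [1.32, 3] plants per-gene effects between 2.5- and 8-fold).  ``genes``
    may be given explicitly; if ``None`` the simulator draws ``size`` genes
    from the tissue's platform universe.
    """

    name: str
    tissue: str
    effects: dict
    genes: frozenset | None = None
    size: int = 100

    def __post_init__(self) -> None:
        if not self.effects:
            raise ValueError(f"program {self.name!r} has no zone effects")
        for z, e in self.effects.items():
            if not np.isfinite(e):
                raise ValueError(f"non-finite effect for zone {z!r} in {self.name!r}")
        if self.genes is not None:
            self.genes = frozenset(fold_symbol(g) for g in self.genes)
            if not self.genes:
                raise ValueError(f"program {self.name!r} has an empty gene set")
            self.size = len(self.genes)
        elif self.size < 1:
            raise ValueError(f"program {self.name!r} needs size >= 1")


@dataclass
class SimulationDesign:
    """Full description of a simulated one- or two-tissue zonal experiment.

    Defaults mirror the study design the package targets: n = 4 replicate
    samples per zone, log2 baselines uniform on [5, 12] (raw signals from a
    few dozen to ~10^4), and replicate noise sd 0.35 log2 units.
    """

    tissues: list = field(default_factory=list)  # [(tissue label, (zones...)), ...]
    n_genes: int = 2000
    n_replicates: int = 4
    baseline_range: tuple = (5.0, 12.0)
    sigma: float = 0.35
    programs: list = field(default_factory=list)
    amplitude_range: tuple = (np.log2(2.5), 3.0)
    correspondences: list = field(default_factory=list)  # [(prog_a, prog_b), ...]
    rho: float = 0.0
    platform_overlap: float = 1.0
    fc_truth_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not 0.0 <= self.platform_overlap <= 1.0:
            raise ValueError("platform_overlap must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per zone")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.fc_truth_threshold < 1:
            raise ValueError("fc_truth_threshold must be >= 1")
        labels = [t for t, _ in self.tissues]
        if len(set(labels)) != len(labels):
            raise ValueError("tissue labels must be unique")
        for tissue, zones in self.tissues:
            if len(set(zones)) != len(zones) or len(zones) < 2:
                raise ValueError(f"tissue {tissue!r} needs >= 2 unique zones")
        zone_of = {t: set(z) for t, z in self.tissues}
        for prog in self.programs:
            if prog.tissue not in zone_of:
                raise ValueError(f"program {prog.name!r} names unknown tissue {prog.tissue!r}")
            bad = set(prog.effects) - zone_of[prog.tissue]
            if bad:
                raise ValueError(f"program {prog.name!r} names unknown zones {sorted(bad)}")

    def zones_of(self, tissue: str):
        for t, zones in self.tissues:
            if t == tissue:
                return tuple(zones)
        raise KeyError(f"unknown tissue {tissue!r}; design has {[t for t, _ in self.tissues]}")

    def zone_pairs(self, tissue: str):
        """All unordered zone pairs of a tissue, in design order."""
        return list(itertools.combinations(self.zones_of(tissue), 2))


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation run.

    ``planted`` maps ``(tissue, (zone_a, zone_b), up_zone)`` to the set of
    genes whose realized effect difference between the two zones is at least
    ``log2(fc_truth_threshold)`` in favour of ``up_zone``.  ``shared_pairs``
    maps pairs of such keys (one per tissue) to the genes deliberately
    shared between the corresponding programs that are planted on both
    sides.
    """

    planted: dict = field(default_factory=dict)
    shared_pairs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (key_a, key_b), genes in self.shared_pairs.items():
            for key in (key_a, key_b):
                if not genes <= self.planted.get(key, frozenset()):
                    raise ValueError(f"shared genes for {key} not a subset of its planted set")

    def planted_for(self, tissue: str, zone_a: str, zone_b: str, up_zone: str) -> frozenset:
        key = (tissue, (zone_a, zone_b), up_zone)
        alt = (tissue, (zone_b, zone_a), up_zone)
        return self.planted.get(key, self.planted.get(alt, frozenset()))

    def all_planted(self, tissue: str) -> frozenset:
        out: set = set()
        for (t, _pair, _dir), genes in self.planted.items():
            if t == tissue:
                out |= genes
        return frozenset(out)

    def to_json_dict(self) -> dict:
        def fmt(key):
            tissue, (za, zb), up = key
            return f"{tissue}|{za}-{zb}|up:{up}"

        return {
            "planted": {fmt(k): sorted(v) for k, v in self.planted.items()},
            "shared_pairs": {
                f"{fmt(ka)} ~ {fmt(kb)}": sorted(v)
                for (ka, kb), v in self.shared_pairs.items()
            },
        }


# ---------------------------------------------------------------------------
# gene universes and program gene assignment
# ---------------------------------------------------------------------------

def _symbol_pool(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"sg{idx:0{width}d}" for idx in range(1, n + 1)]


def _platform_universes(design: SimulationDesign, rng: np.random.Generator):
    """Two same-size universes sharing ``platform_overlap`` of their genes."""
    n = design.n_genes
    n_shared = int(round(design.platform_overlap * n))
    pool = np.array(_symbol_pool(2 * n - n_shared))
    rng.shuffle(pool)
    shared = list(pool[:n_shared])
    uniq_a = list(pool[n_shared:n])
    uniq_b = list(pool[n : 2 * n - n_shared])
    return shared + uniq_a, shared + uniq_b, shared


def _draw(rng: np.random.Generator, pool: list, k: int) -> list:
    if k > len(pool):
        raise ValueError(f"cannot draw {k} genes from a pool of {len(pool)}")
    return list(rng.choice(np.array(pool, dtype=object), size=k, replace=False))


def _assign_program_genes(design: SimulationDesign, universes: dict, shared: list,
                          rng: np.random.Generator):
    """Concrete gene sets per program plus the deliberately shared sets.

    Programs of one tissue are pairwise disjoint.  For corresponded program
    pairs a deliberate share of size round(rho * min(sizes)) is drawn from
    the cross-platform shared pool; the remainder of each program is drawn
    independently from its own universe, so at rho = 0 corresponding
    programs are independent draws (overlapping only by chance).
    """
    genes: dict[str, frozenset] = {}
    used: dict[str, set] = {t: set() for t in universes}
    deliberate: dict[tuple, frozenset] = {}
    program_share: dict[str, set] = {}
    by_name = {p.name: p for p in design.programs}

    for name_a, name_b in design.correspondences:
        if name_a not in by_name or name_b not in by_name:
            raise ValueError(f"correspondence names unknown program: {(name_a, name_b)}")
        a, b = by_name[name_a], by_name[name_b]
        if a.tissue == b.tissue:
            raise ValueError("corresponding programs must belong to different tissues")
        if a.genes is not None or b.genes is not None:
            raise ValueError("correspondences require simulator-assigned gene sets")
        m = int(round(design.rho * min(a.size, b.size)))
        for prog in (a, b):
            have = len(program_share.get(prog.name, set()))
            if have + m > prog.size:
                raise ValueError(
                    f"program {prog.name!r} cannot honor rho={design.rho} across "
                    f"its correspondences ({have} + {m} shared > size {prog.size})")
        pool = [g for g in shared if g not in used[a.tissue] and g not in used[b.tissue]]
        share = _draw(rng, pool, m)
        deliberate[(name_a, name_b)] = frozenset(share)
        for prog in (a, b):
            program_share.setdefault(prog.name, set()).update(share)
            used[prog.tissue] |= set(share)

    for prog in design.programs:
        base = program_share.get(prog.name, set())
        if prog.genes is not None:
            missing = prog.genes - set(universes[prog.tissue])
            if missing:
                raise ValueError(
                    f"program {prog.name!r} genes absent from the {prog.tissue!r} "
                    f"universe: {sorted(missing)[:5]}"
                )
            genes[prog.name] = prog.genes
        else:
            own = [g for g in universes[prog.tissue] if g not in used[prog.tissue]]
            rest = _draw(rng, own, prog.size - len(base))
            genes[prog.name] = frozenset(base) | frozenset(rest)
        used[prog.tissue] |= set(genes[prog.name])
    return genes, deliberate


# ---------------------------------------------------------------------------
# matrix generation and truth bookkeeping
# ---------------------------------------------------------------------------

def _realized_effects(design: SimulationDesign, tissue: str, universe: list,
                      program_genes: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene realized log2 effect for every zone of one tissue."""
    zones = design.zones_of(tissue)
    idx = {g: i for i, g in enumerate(universe)}
    eff = np.zeros((len(universe), len(zones)))
    lo, hi = design.amplitude_range
    for prog in design.programs:
        if prog.tissue != tissue:
            continue
        members = sorted(program_genes[prog.name])
        amp = rng.uniform(lo, hi, size=len(members))
        rows = np.array([idx[g] for g in members], dtype=int)
        for j, z in enumerate(zones):
            e = prog.effects.get(z, 0.0)
            if e:
                eff[rows, j] += e * amp
    return pd.DataFrame(eff, index=universe, columns=list(zones))


def _truth_from_effects(design: SimulationDesign, tissue: str,
                        effects: pd.DataFrame) -> dict:
    thr = np.log2(design.fc_truth_threshold)
    planted: dict = {}
    for za, zb in design.zone_pairs(tissue):
        d = effects[za] - effects[zb]
        planted[(tissue, (za, zb), za)] = frozenset(effects.index[d >= thr])
        planted[(tissue, (za, zb), zb)] = frozenset(effects.index[-d >= thr])
    return planted


def _simulate_matrix(design: SimulationDesign, tissue: str, universe: list,
                     effects: pd.DataFrame, rng: np.random.Generator) -> ExpressionMatrix:
    zones = design.zones_of(tissue)
    n_genes, n_rep = len(universe), design.n_replicates
    mu = rng.uniform(*design.baseline_range, size=n_genes)
    cols, data = [], []
    records = []
    for z in zones:
        base = mu + effects[z].to_numpy()
        for r in range(1, n_rep + 1):
            sample_id = f"{tissue}_{z}_r{r}"
            cols.append(sample_id)
            records.append({"sample_id": sample_id, "tissue": tissue,
                            "zone": z, "replicate": f"r{r}"})
            data.append(base + rng.normal(0.0, design.sigma, size=n_genes))
    values = pd.DataFrame(np.column_stack(data), index=universe, columns=cols)
    return ExpressionMatrix(values, pd.DataFrame(records), platform=tissue)


def simulate_dataset(design: SimulationDesign, tissue: str):
    """Simulate one tissue's log2 expression matrix plus its ground truth.

    Values are ``baseline + realized zone effect + N(0, sigma^2)``.  The
    truth records, per zone pair and direction, exactly the genes whose
    realized effect difference reaches ``log2(fc_truth_threshold)``.
    """
    zones = design.zones_of(tissue)  # raises on unknown tissue
    del zones
    universe = _symbol_pool(design.n_genes)
    rng = _substream(design.seed, "assign", tissue)
    program_genes, _ = _assign_program_genes(
        SimulationDesign(**{**design.__dict__, "correspondences": [], "programs":
                            [p for p in design.programs if p.tissue == tissue]}),
        {tissue: universe}, universe, rng)
    effects = _realized_effects(design, tissue, universe, program_genes,
                                _substream(design.seed, "effects", tissue))
    matrix = _simulate_matrix(design, tissue, universe, effects,
                              _substream(design.seed, "matrix", tissue))
    truth = SyntheticTruth(planted=_truth_from_effects(design, tissue, effects))
    return matrix, truth


def simulate_tissue_pair(design: SimulationDesign):
    """Simulate two tissues on partially overlapping platforms.

    Returns ``(matrix_a, matrix_b, truth)`` where the truth's
    ``shared_pairs`` links corresponding planted directional gene sets via
    the deliberately shared genes (fraction ``rho`` of each corresponding
    program, drawn from the cross-platform shared pool).
    """
    if len(design.tissues) != 2:
        raise ValueError(f"need exactly 2 tissues, got {len(design.tissues)}")
    (tissue_a, _), (tissue_b, _) = design.tissues
    uni_a, uni_b, shared = _platform_universes(design, _substream(design.seed, "universe"))
    universes = {tissue_a: uni_a, tissue_b: uni_b}
    program_genes, deliberate = _assign_program_genes(
        design, universes, shared, _substream(design.seed, "assign"))

    matrices, planted = {}, {}
    for tissue in (tissue_a, tissue_b):
        effects = _realized_effects(design, tissue, universes[tissue], program_genes,
                                    _substream(design.seed, "effects", tissue))
        matrices[tissue] = _simulate_matrix(design, tissue, universes[tissue], effects,
                                            _substream(design.seed, "matrix", tissue))
        planted.update(_truth_from_effects(design, tissue, effects))

    shared_pairs: dict = {}
    keys_a = [k for k in planted if k[0] == tissue_a]
    keys_b = [k for k in planted if k[0] == tissue_b]
    for (name_a, name_b), share in deliberate.items():
        if not share:
            continue
        for ka in keys_a:
            common_a = share & planted[ka]
            if not common_a:
                continue
            for kb in keys_b:
                common = common_a & planted[kb]
                if common:
                    shared_pairs[(ka, kb)] = frozenset(common)
    truth = SyntheticTruth(planted=planted, shared_pairs=shared_pairs)
    return matrices[tissue_a], matrices[tissue_b], truth


# ---------------------------------------------------------------------------
# qPCR and probe-level simulators
# ---------------------------------------------------------------------------

def simulate_qpcr(effect_profile: dict, n_animals: int = 4, noise_sd: float = 0.3,
                  seed: int = 0, reference_gene: str = "18S",
                  n_replicates: int = 3, base_ct: float = 12.0,
                  target_offset: float = 8.0) -> QpcrTable:
    """Simulate a threshold-cycle (CT) table for a zonal qPCR experiment.

    ``effect_profile`` maps each measured gene (the housekeeping reference
    included, normally with all-zero effects) to a map zone -> log2 fold
    versus the reference zone.  Each animal gets its own baseline CT; each
    (animal, zone, gene) is measured in ``n_replicates`` technical
    replicates with ``noise_sd`` cycles of Gaussian noise.  A planted +1
    log2 effect lowers CT by one cycle, i.e. doubles relative expression.
    """
    if n_animals < 2:
        raise ValueError("need at least 2 animals")
    if reference_gene not in effect_profile:
        raise KeyError(f"reference gene {reference_gene!r} missing from effect profile")
    zones = list(effect_profile[reference_gene])
    for gene, prof in effect_profile.items():
        if set(prof) != set(zones):
            raise ValueError(f"gene {gene!r} zones differ from reference zones {zones}")
    rng = _substream(seed, "qpcr")
    animal_base = base_ct + rng.normal(0.0, 0.5, size=n_animals)
    rows = []
    for i in range(n_animals):
        animal = f"a{i + 1}"
        for zone in zones:
            for gene, prof in effect_profile.items():
                offset = 0.0 if gene == reference_gene else target_offset
                mean_ct = animal_base[i] + offset - prof[zone]
                noise = rng.normal(0.0, noise_sd, size=n_replicates) if noise_sd > 0 \
                    else np.zeros(n_replicates)
                for r in range(n_replicates):
                    rows.append({"animal": animal, "zone": zone, "gene": gene,
                                 "replicate": r + 1, "ct": mean_ct + noise[r]})
    return QpcrTable(pd.DataFrame(rows), reference_gene=reference_gene)


def simulate_probe_matrix(gene_values: pd.DataFrame, n_probes_per_gene: int,
                          probe_offsets, noise_sd: float = 0.0,
                          seed: int = 0) -> ProbeMatrix:
    """Expand a log2 gene x sample matrix into a linear-scale probe matrix.

    Each gene gets ``n_probes_per_gene`` probes; probe p of every gene adds
    ``probe_offsets[p]`` (log2 units, probe affinity) plus Gaussian noise,
    and the result is antilogged to linear intensities.  Median polish on
    the log2 of the output recovers the gene values up to the additive
    probe-effect convention.
    """
    if n_probes_per_gene < 1:
        raise ValueError("n_probes_per_gene must be >= 1")
    offsets = np.asarray(probe_offsets, dtype=float)
    if offsets.shape != (n_probes_per_gene,):
        raise ValueError(
            f"probe_offsets has shape {offsets.shape}, expected ({n_probes_per_gene},)")
    rng = _substream(seed, "probes")
    rows, index, mapping = [], [], {}
    for gene in gene_values.index:
        base = gene_values.loc[gene].to_numpy(dtype=float)
        for p in range(n_probes_per_gene):
            probe_id = f"{gene}_p{p + 1}"
            noise = rng.normal(0.0, noise_sd, size=base.size) if noise_sd > 0 \
                else np.zeros(base.size)
            rows.append(2.0 ** (base + offsets[p] + noise))
            index.append(probe_id)
            mapping[probe_id] = str(gene)
    values = pd.DataFrame(np.vstack(rows), index=index, columns=gene_values.columns)
    return ProbeMatrix(values, pd.Series(mapping, name="gene"))


# ---------------------------------------------------------------------------
# canonical study design
# ---------------------------------------------------------------------------

def default_study_design(seed: int = 0, n_genes: int = 2000, program_size: int = 100,
                         rho: float = 0.8, platform_overlap: float = 0.8,
                         sigma: float = 0.35, n_replicates: int = 4) -> SimulationDesign:
    """Two-tissue design mirroring the articular / growth-plate study.

    Articular cartilage (AC) has superficial (SZ) and intermediate/deep
    (IDZ) zones; growth-plate cartilage (GP) has resting (RZ),
    proliferative (PZ), and hypertrophic (HZ) zones.  One program is planted
    per zone, and the correspondences encode the headline biological finding
    the inference should recover: the SZ program shares genes with the HZ
    program and the IDZ program with the RZ program.  (A program cannot
    honor two full-rho shares at rho > 0.5, so the secondary SZ~PZ
    similarity is not planted by default.)
    """
    programs = [
        ZoneProgram("sz_program", "AC", {"SZ": 1.0}, size=program_size),
        ZoneProgram("idz_program", "AC", {"IDZ": 1.0}, size=program_size),
        ZoneProgram("rz_program", "GP", {"RZ": 1.0}, size=program_size),
        ZoneProgram("pz_program", "GP", {"PZ": 1.0}, size=program_size),
        ZoneProgram("hz_program", "GP", {"HZ": 1.0}, size=program_size),
    ]
    return SimulationDesign(
        tissues=[("AC", ("SZ", "IDZ")), ("GP", ("RZ", "PZ", "HZ"))],
        n_genes=n_genes,
        n_replicates=n_replicates,
        sigma=sigma,
        programs=programs,
        correspondences=[("sz_program", "hz_program"),
                         ("idz_program", "rz_program")],
        rho=rho,
        platform_overlap=platform_overlap,
        seed=seed,
    )
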