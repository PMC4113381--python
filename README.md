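# zonemap

Zonal transcriptome correspondence for spatially stratified tissues.

Layered tissues — the motivating case is cartilage, with articular
cartilage stratified into superficial (SZ) and intermediate/deep (IDZ)
zones and growth-plate cartilage into resting (RZ), proliferative (PZ),
and hypertrophic (HZ) zones — can be profiled zone by zone after
microdissection. When two such experiments are run on different array
platforms, expression levels cannot be compared directly, but the *gene
lists* that distinguish zones can. `zonemap` implements that inference
end to end for anyone asking "which zone of tissue A is transcriptionally
most similar to which zone of tissue B?":

1. **Probe summarization** — quantile normalization across arrays and
   Tukey median-polish summarization of log2 probe intensities into one
   expression value per gene and sample.
2. **Spatial differential expression** — a gene is *spatially regulated*
   between two zones when its geometric-mean expression differs ≥ 2-fold
   with a one-way ANOVA false discovery rate < 0.05
   (Benjamini–Hochberg), yielding two disjoint directional gene lists per
   zone pair.
3. **Cross-platform correspondence** — over the universe of N genes
   present on both platforms, the overlap k of directional lists of sizes
   n_a and n_b is tested against the independence expectation
   E = n_a·n_b/N with a Pearson chi-square on the 2×2 membership table
   (df = 1, no continuity correction); the 12-comparison family (2
   articular directions × 6 growth-plate directional lists) is corrected
   with the Holm–Šidák method, and each overlap is labelled more than /
   less than / consistent with chance.
4. **Marker localization** — known zonal marker sets are counted inside
   each directional list (k of K markers) with the same chi-square
   enrichment test.
5. **Sample structure** — PCA of samples on gene-centered data and
   average-linkage hierarchical clustering on per-gene z-scores of the DE
   genes.
6. **qPCR validation** — ΔΔCT relative expression,
   `2^-(CT_gene - CT_ref) × 10^6`, with repeated-measures ANOVA and
   paired t-tests on log2 values for predetermined zone comparisons.

Every stage is testable without external data through a seeded,
truth-annotated synthetic generator (`zonemap.simulate`) that emulates
the study design: n = 4 replicates per zone, log2 baselines on [5, 12],
replicate noise σ = 0.35 log2 units, planted zone programs of ≥ 2.5-fold
effects, and two platforms with a controlled gene-universe overlap and a
controlled fraction ρ of deliberately shared program genes.

## Worked example

```python
import zonemap as zm

design = zm.default_study_design(seed=11, n_genes=2000, program_size=100,
                                 rho=0.8, platform_overlap=0.8)
articular, growth_plate, truth = zm.simulate_tissue_pair(design)

table, up_sz, up_idz = zm.call_spatially_regulated(articular, "SZ", "IDZ")
print(f"{len(up_sz)} genes up in SZ, {len(up_idz)} up in IDZ "
      f"(of {len(table)} tested)")

lists_gp = []
for za, zb in design.zone_pairs("GP"):
    _, ua, ub = zm.call_spatially_regulated(growth_plate, za, zb)
    lists_gp += [ua, ub]

universe = zm.intersect_universe(articular.gene_universe,
                                 growth_plate.gene_universe)
print(f"shared universe: {len(universe)} genes")

results = zm.all_pairs_correspondence([up_sz, up_idz], lists_gp, universe)
for r in results:
    if r.direction != "none":
        print(f"{r.list_a_id} ~ {r.list_b_id}: k={r.k} expected={r.expected:.1f} "
              f"chi2={r.chi2:.1f} p_adj={r.p_adj:.2e} {r.direction}")
```

prints

```
99 genes up in SZ, 97 up in IDZ (of 2000 tested)
shared universe: 1600 genes
AC:SZ>(SZ-IDZ) ~ GP:HZ>(RZ-HZ): k=78 expected=5.6 chi2=1062.2 p_adj=6.67e-232 more_than_chance
AC:SZ>(SZ-IDZ) ~ GP:HZ>(PZ-HZ): k=78 expected=5.6 chi2=1050.3 p_adj=2.25e-229 more_than_chance
AC:IDZ>(SZ-IDZ) ~ GP:RZ>(RZ-PZ): k=78 expected=5.7 chi2=1037.2 p_adj=1.48e-226 more_than_chance
AC:IDZ>(SZ-IDZ) ~ GP:RZ>(RZ-HZ): k=78 expected=5.7 chi2=1037.2 p_adj=1.48e-226 more_than_chance
```

The DE caller recovers essentially all planted program genes (~100 per
direction), and the overlap family flags exactly the planted
correspondences — the articular SZ program shared with the growth-plate
HZ program, and the IDZ program shared with the RZ program — as
containing far more common genes (k = 78) than the ~6 expected by chance,
while the other eight comparisons stay non-significant.

## Command line

The same stages are available as subcommands of the `zonemap` console
script: `simulate`, `normalize`, `de`, `correspond`, `structure`, `qpcr`,
`simulate-qpcr`, and `run-all` (YAML-config-driven, writing all artifacts
plus a deterministic `manifest.json` and `run.log`). For example:

```sh
zonemap simulate --outdir sim --seed 2 --n-genes 2000
zonemap de --matrix sim/expression_AC.tsv --sample-sheet sim/samples_AC.tsv \
       --zone-a SZ --zone-b IDZ --out de_ac.tsv
zonemap run-all --config config.yaml
```

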