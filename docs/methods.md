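# Methods notes

## The analysis model

`zonemap` treats a zonal expression experiment as a genes × samples
matrix of log2 intensities in which each sample belongs to one zone of
one tissue, with a fixed replicate count per zone. Three inferential
layers sit on top:

**Spatial differential expression.** For a zone pair (a, b) each gene is
tested with a classical fixed-effects one-way ANOVA on its log2 values in
the two zones (with two groups this is identically the pooled-variance
two-sample t-test, F = t²). Raw p-values are converted to q-values with
the Benjamini–Hochberg step-up procedure *within the zone pair's family*
(each pair is treated as a separate comparison, so q-values are not
pooled across pairs). A gene is called spatially regulated when its
fold-change — the ratio of antilogged group means, i.e. of geometric
means, which matches how raw-signal pairs convert to printed integer
fold-changes in array reports — is at least `fc_threshold` (default 2)
and its q is below `q_threshold` (default 0.05). The called genes split
into two disjoint directional lists by the sign of the mean difference.
The ANOVA is fitted per zone pair rather than jointly across all zones
with contrasts; the criterion is inherently pairwise and this keeps the
q-value family aligned with the reported comparisons.

**Cross-platform correspondence.** Directional lists from two
experiments are compared only through membership over the shared
universe: the case-insensitive intersection of the two platforms' gene
sets (gene identity is case-folded symbol equality, since annotation
casing differs between platforms). For lists of sizes n_a, n_b over N
universe genes with observed overlap k, the 2×2 membership table
(k, n_a−k, n_b−k, N−n_a−n_b+k) is tested with Pearson's chi-square,
df = 1, **no** Yates continuity correction — expected cells are large in
the intended regime (N in the thousands) and the uncorrected statistic
equals the squared two-proportion z statistic exactly. The canonical
family is the 12 comparisons of two articular directions against six
growth-plate directional lists; the family is corrected with the
Holm–Šidák step-down method (adj_(i) = 1 − (1 − p_(i))^(m−i+1), monotone,
capped at 1) and a direction (more / less than chance) is assigned only
when the adjusted p clears alpha. Marker-set localizations are reported
individually without family correction, as marker censuses conventionally
are; both choices are configurable.

**qPCR zone statistics.** Relative expression is
2^−(CT_gene − CT_ref) × 10⁶ against a housekeeping reference; the 10⁶
factor is cosmetic and cancels in all comparisons. Technical triplicates
are collapsed by mean CT *before* biological statistics (collapsing at
the relative-expression level instead changes results only through
Jensen-type curvature and is not offered). Inference runs on log2
relative expression: a repeated-measures one-way ANOVA with animal as the
subject factor (statsmodels `AnovaRM`; no sphericity correction, a
deliberate simplification at n = 4 animals and ≤ 5 zones), followed by
two-sided paired t-tests for the predetermined zone pairs.

## Normalization components

Only the two summarization components of robust multi-array average are
implemented; probe-level background correction needs raw probe files the
package does not consume, so its input is an already-extracted positive
probe × sample intensity matrix.

*Quantile normalization* maps every column onto the per-rank means of the
column-sorted matrix. Ties receive the mean of the tied ranks' reference
values. Note a consequence of that standard tie rule: a column with
exact ties ends up with a value multiset that differs from the reference
at the tied ranks, so strict idempotence holds only for tie-free columns
(continuous intensities are tie-free almost surely; the test suite
asserts idempotence on tie-free data and the tie rule separately).

*Median polish* decomposes one gene's probes × samples block into grand +
probe effect + sample effect + residual by alternately sweeping row and
column medians (rows first), stopping when the largest absolute effect
change falls below `tol = 1e-6` or after `max_iter = 10` full sweeps.
The reconstruction is exact by construction at any iteration count; the
per-sample gene summary is grand + column effect. Effects are
median-centered (a median-zero, not sum-zero, convention — the choice is
irrelevant to the summaries, which absorb any additive constant).

## The synthetic generator

The generator is the package's stand-in for the microarray study and
defines the conditions under which every recovery claim is made:

- two tissues with ordered zones (canonically AC: SZ, IDZ and GP: RZ,
  PZ, HZ), **n = 4** replicates per zone;
- per-gene log2 baselines uniform on **[5, 12]**, spanning raw signals
  from a few dozen to ~10⁴ as in typical array report tables;
- replicate noise N(0, σ²) with **σ = 0.35** log2 units — at n = 4 this
  gives high but not saturating power for 2-fold effects, the regime the
  calling rule is designed for (no per-zone variance estimates exist to
  fit σ to, so it is declared, not inferred);
- zone programs: gene sets with a per-zone log2 profile, each member
  gene scaling the profile by an amplitude drawn uniform on
  **[log2 2.5, 3]** (2.5- to 8-fold), a realistic spread bracketing the
  2–25-fold range of published zonal tables;
- two platforms built by sampling symbols from a shared pool so that a
  fraction `platform_overlap` of each universe is common;
- corresponding programs across tissues share a deliberately common
  subset of fraction **ρ**, drawn from the shared pool; the remainder of
  each program is drawn *independently*, so ρ = 0 is the independence
  null (not forced disjointness, which would plant depletion). One
  program cannot honor two correspondences at ρ > 0.5; the generator
  raises rather than silently capping, and the default study design
  therefore plants the two headline correspondences (SZ~HZ, IDZ~RZ).

Ground truth records, per tissue, zone pair and direction, exactly the
genes whose realized effect difference reaches log2 of the declared
fold threshold, plus the deliberately shared gene sets linking planted
directional lists across tissues.

All randomness flows from one integer seed through labelled CRC32-derived
substreams (universe construction, program assignment, per-tissue
effects, per-tissue matrices, qPCR, probes), so each artifact is
individually reproducible.

What the generator does **not** emulate: probe-level optical background
and GC effects, correlated (pathway-structured) noise between genes,
platform-specific probe affinities, batch effects within an experiment,
and cross-hybridization. Recovery results on synthetic data therefore
certify the inferential machinery under its stated assumptions, not
performance on raw array data.

## Benchmark problem sizes

The self-benchmarks in `zonemap.evaluate` (used by the test suite and
`scripts/acceptance.py`) run at sizes chosen as a faithful scaled-down
image of the study design: spatial-DE recovery on 10,000 genes with 500
planted ≥ 2.5-fold genes (2 zones × 4 replicates, σ = 0.35);
correspondence recovery and the null familywise-error study on 1,000
genes with programs of 100 genes, so the chance-expected overlap
n_a·n_b/N ≈ 10 keeps expected chi-square cells comfortably large (the
textbook adequacy rule); 500 replicates for the type-I estimate.

## Numerical and degenerate-input conventions

- ANOVA with zero residual variance: equal means → (F = 0, p = 1);
  unequal means → (F = ∞, p = 0) with a warning.
- Overlap tests with a zero margin (empty list or list = universe) are
  flagged degenerate with p = NA; degenerate results are excluded from
  the Holm–Šidák family size.
- Direction "none" is reported when k equals its expectation exactly,
  regardless of p.
- Constant genes z-score to an all-zero row and are reported; z-scores
  use the n−1 (sample) standard deviation.
- Clustering sorts samples lexicographically by id before linkage so
  distance ties break deterministically; default metric/linkage is
  Euclidean-on-z-scores with average linkage (configurable — the choice
  is conventional, not identifiable from published dendrograms).
- PCA runs on gene-centered (not standardized) data by default, with a
  correlation-mode option.
- Duplicate gene symbols collapse to the smallest-p row when DE context
  exists, else to the highest-mean row.
- Result tables render floats at 6 significant digits and NaN as "NA";
  manifest JSON is key-sorted and timestamp-free so identical configs
  and seeds produce byte-identical outputs.

## Design shape

The operations that are genuinely transform-shaped expose sklearn-style
estimators (`QuantileNormalizer`; PCA and clustering delegate to
scikit-learn/scipy), and `SpatialDECaller` follows the
fit-then-underscore-attributes idiom with `get_params`/`set_params`. The
hypothesis tests, tabulations, simulation, and orchestration are plain
functions over typed containers — forcing a fit/predict interface onto a
chi-square overlap test or a ΔΔCT table would obscure, not compose.

## Known limitations

- The pairwise ANOVA + per-pair BH family is one reading of the calling
  rule; a joint multi-zone ANOVA with contrasts and experiment-wide FDR
  is a defensible alternative and would be slightly more conservative.
- The chi-square overlap test is asymptotic; for small universes or
  short lists a hypergeometric (Fisher) test would be exact. It is
  intentionally not offered as the default because the method being
  implemented specifies Pearson's chi-square.
- No moderated-variance (shrinkage) DE estimator and no batch
  covariates.
- qPCR assumes perfect amplification efficiency (the exponent base 2)
  and a stable reference gene.
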