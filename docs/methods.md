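# Methods

`rhizomine` reconstructs the taxonomic and functional diversity of
root-associated microbiota from the non-host fraction of a plant
RNA-seq experiment, and relates it to the host design and transcriptome
with standard community-ecology statistics. This note documents the
models and procedures, the defaults and why they are what they are, the
numerical choices, and what the synthetic-data tests do and do not
establish.

## Study design assumed by the defaults

The package is organized around a 2 × 3 × 3 design: two tomato
genotypes (`B`, resistant to Fusarium wilt; `C`, susceptible) grown in
two native field soils (`AL`, disease-suppressive; `RO`, conducive) and
a disinfected peat substrate (`CONT`), with three biological replicates
— 18 samples of 50 bp single-end RNA-seq. Nothing in the library code
hard-wires these labels except the synthetic generator's sample sheet
and the pipeline's default PERMANOVA terms (`genotype`, `soil`,
`genotype:soil`), all overridable.

## Read-to-taxon assignment

Alignment hits (BLAST-tabular with subject taxids) are resolved per
read:

1. hits below `min_identity` (default **97%**, the conventional
   species-level similarity threshold for short reads) are discarded;
2. hits outside `score_margin` (default **0**: strict best-score ties)
   of the best surviving bit score are discarded; score equality is
   judged at 1e−9 relative tolerance because scores come from text;
3. a single surviving taxid is assigned directly (nearest neighbor);
   several distinct taxids are promoted to their lowest common ancestor
   on the reference taxonomy.

This gives conservative assignments: a read hitting two sibling species
equally well is counted at their genus. Hits naming taxids absent from
the taxonomy (stale database entries) are dropped per hit with a logged
warning, never a crash; an optional merged-taxid table can remap them
first. Reads from contaminant lineages are still assigned here —
exclusion is a table-level step, preserving the pipeline's stage order.

Guarantees verified by tests: each read contributes exactly one count
(assigned + unassigned = reads, always); raising `min_identity` never
increases the assigned count; raising `score_margin` only moves
assignments rootward; with noise-free unambiguous hits, accuracy is
100%.

## Pseudo-reads

50 bp reads carry too little signal for protein-level (orthology)
annotation, so each mapped interval is widened by `flank` (default
**50 bp**) on both sides along its reference and the range is
extracted, yielding 150 bp pseudo-reads for interior reads. Coordinates
are 0-based half-open (BED convention) internally; the BLAST-tabular
parser converts from 1-based inclusive and infers strand from reversed
subject coordinates. Extension clips at reference bounds, so
`extract ∘ extend` can never fail on a valid interval; clipped
pseudo-reads shorter than 60 nt are kept but flagged. Strand is ignored
by default (plain range extraction); `honor_strand` reverse-complements
minus-strand intervals. Redundant HSPs are removed per (read, subject)
pair keeping the best score, ties broken by ascending subject
coordinates for determinism. Pooled pseudo-reads keep provenance as
`sample|read_id`.

## Count tables

Stage order: contaminant removal → low-abundance filter → rank
aggregation → normalization.

* **Contaminant removal** drops features whose lineage passes through
  any excluded root (defaults: Viridiplantae 33090 and Metazoa 33208,
  the host/animal lineages of a plant root meta-transcriptome).
* **Low-abundance filter**: a feature is *retained* iff it has
  ≥ `min_count` (5) raw reads in ≥ `min_samples` (3) libraries,
  counted over all samples. The complementary reading of the rule
  ("remove if < 5 reads in ≥ 3 of 18 libraries") would delete
  essentially every real taxon, so retention is the implemented
  direction. The filter runs on raw counts by design.
* **Rank aggregation** (default family) sums counts into each
  feature's ancestor at the target rank. Lineages lacking the rank go
  to a single `unranked` bucket rather than being promoted to a nearby
  rank — promotion would silently distort family-level tables — so
  column totals are conserved exactly.
* **Normalization** is median-of-ratios: for each feature positive in
  every sample, the ratio of each sample's count to the feature's
  geometric mean is formed; a sample's size factor is the median of
  its ratios. Geometric means accumulate in log space (underflow); the
  median is taken in linear space, which is the estimator's literal
  definition (log-space medians differ at even feature counts). Size
  factors are defined up to a common multiplier; the equivariance
  guarantee tested is therefore on factor ratios.

## Differential abundance

A deliberately transparent negative-binomial Wald contract, not a port
of any shrinkage-based package: per-feature pooled method-of-moments
dispersion `alpha = max(0, (var − mu)/mu²)`, delta-method standard
error of the log fold change with NB variance `mu + alpha·mu²`, and a
**t reference with nA + nB − 2 degrees of freedom** — the normal
reference is visibly anticonservative at the 3–9 replicates this
design has. A half-count offset keeps zero-mean groups finite.
Benjamini–Hochberg adjustment; positive log2 fold change means
enrichment in the first contrast level. Measured behavior: null
rejection at p<0.05 is 0.049 (100 seeded null tables, 50 features,
6 per group); with ten 4-fold features among 200 nulls the true
features dominate the top ranks and empirical FDR at the 0.05 cutoff
stays within twice nominal over 20 replicates. The row schema is an
adapter seam: an external NB-GLM implementation can be substituted
without touching downstream code.

## Community statistics

**Bray–Curtis** `d_jk = Σ|x_ij − x_ik| / Σ(x_ij + x_ik)` on normalized
profiles; all-zero samples are an error (the dissimilarity is undefined
there).

**PERMANOVA** partitions the Gower-centered matrix of squared
distances (McArdle–Anderson direct method): for the cumulative design
projectors `H_k`, the sequential (Type-I) SS of term k is
`trace((H_k − H_{k−1}) G)`, in the order Genotype, Soil,
Genotype × Soil. Pseudo-F is MS_term/MS_residual; p-values come from
free permutation of sample labels (no strata; none are called for by a
fully randomized pot design), `p = (1 + #{F* ≥ F}) / (1 + n_perm)`
with `n_perm` = 999 by default. Two numerical details: dummy coding is
redundant (full indicator blocks) with projectors built by
pseudoinverse, so factor-level bookkeeping cannot create rank bugs;
and the exceedance comparison carries a 1e−8 tolerance to absorb
round-off between the permuted and observed code paths (identical
relabelings must count as ties). An explicit permutation array can be
supplied, in which case p is the exact fraction over that set — used
for full-enumeration checks at small n. The implementation reproduces
vegan's `adonis2` SS, R² and F to 1e−6 on the same input, and its
genotype-term type-I error over 200 seeded null datasets is 2–5.5%
depending on the seed range (nominal 5%). R² is SS/SS_total, so the
explained-variance-% column is 100·R²; the table derivation is exposed
separately (`finalize_permanova_table`) so a printed Df/SS table can
be completed and checked for internal consistency.

**NMDS** minimizes Kruskal stress-1 by SMACOF with monotone
regression, starting from the classical-scaling (principal
coordinates) configuration plus `n_starts − 1` random restarts. The
deterministic start makes the result exactly invariant to sample
relabeling and usually wins; the restarts guard against local minima.

**Pathway enrichment** is the one-tailed hypergeometric tail for each
pathway's overlap with a selected set of orthology ids within a
universe, BH-adjusted, flagged at raw p < 0.1 (the screening threshold
conventional for this analysis). A two-column KO↔COG mapping reader
and inverter handle the identifier translation.

## Variance partitioning

Redundancy analysis: R² is the fraction of the response's centered
total sum of squares captured by least-squares projection on the
(centered) explanatory block; the Ezekiel adjustment
`1 − (1 − R²)(n − 1)/(n − p − 1)` uses the block's rank `p`.
Projection by `lstsq`/rank, so R² is invariant to any invertible
linear recoding of a block. For 2–4 sets, adjusted R² of every
non-empty union feeds inclusion–exclusion
(`c(S) = Σ_{W⊆S} (−1)^{|S|−|W|} h(W)` with
`h(W) = adjR²(full) − adjR²(full∖W)`), giving unique and shared
fractions that, with the residual, sum to 1 exactly. Slightly negative
fractions are a known artifact of the adjustment and are reported
as-is, never clipped. Unique fractions are tested by partial
(sequential) RDA with free permutation of response rows; shared
fractions are not testable; a set adding no rank beyond the others
gets NaN. The response is used as normalized counts, optionally
Hellinger-transformed (`hellinger()`, the standard pre-transform that
makes Euclidean projection behave on abundances) — the transform is a
flag, not forced, since the appropriate choice depends on the response.

**Forward selection** is greedy on R² gain with three guards: a global
pre-test (the model with every candidate must itself be significant at
`alpha`, otherwise best-of-k selection inflates the type-I error
roughly k-fold — measured 20% → 4% on 5 null candidates), a
permutation test of each admitted variable's partial F given the
current set, and the adjusted-R² ceiling of the global model. The
ceiling is not applied to the first admission: with many noise
candidates the global model's adjustment penalty can fall below a
single strong variable's adjusted R², and refusing the first, already
permutation-validated variable on that ground would return an empty
selection exactly when there is unambiguous signal. Selection is
applied per explanatory set, not on pooled candidates.

Recovery, measured: two sets constructed with unique fractions 0.35
and 0.10 and shared fraction 0.20 at n = 18 are recovered to within
±0.02 on the mean over 50 seeds (the test band is ±0.08).

## Mycorrhizal colonization

From per-segment microscopy scores (colonization class 0–5, arbuscule
class A0–A3; 60 segments per plant in the assumed design):
`F = 100(N − n0)/N`; `M = Σ c(s)/N` with class midpoints
95/70/30/5/1; `m = M·N/(N − n0)`; `a` weights each arbuscule class's
share of the colonized intensity by 100/50/10; `A = a·M/100`
identically. Both coefficient vectors are arguments — they encode the
standard visual-estimation convention, and a lab using different class
boundaries can substitute its own. Verified invariants: all outputs in
[0, 100]; `m ≥ M` with equality at full colonization; adding an
uncolonized segment strictly decreases F, M and A and never increases
anything.

## Synthetic data

Every pipeline input has a seeded generator with recorded ground
truth: a ranked taxonomy with microbial clades plus small
Viridiplantae/Metazoa contaminant clades; per-read alignment hits with
configurable identity noise (N(98, sd), clipped) and sibling-hit
ambiguity (probability of an equal-score second hit forcing LCA
promotion — the truth table records the expected promoted taxon);
negative-binomial count tables over the 18-sample design with
log-normal feature baselines, log-normal sample depths (sd 0.3), NB
dispersion 0.2, and a multiplicative genotype effect on a flagged
feature subset; random references with uniformly placed 50 bp
intervals that always include flush-to-boundary placements. Each
generator draws from a single RNG stream derived from (seed, generator
name), so adding a generator never perturbs existing fixtures, and
identical configs are bit-reproducible.

What the generators do *not* emulate: real sequence evolution, quality
scores, compositional correlation between taxa, library-specific
GC/length biases, or the extreme sparsity of real meta-transcriptome
tables. Passing tests therefore establish the *algorithms'* contracts
(conservation, monotonicity, calibration, oracle equivalence) — not
that any particular biological dataset would yield any particular
table.

## Problem sizes used in the test battery

Simulation-based checks run at sizes chosen to make their statistical
assertions stable while keeping the suite quick: 200 replicates for
PERMANOVA type-I calibration, 50 for power and variance-fraction
recovery, 100 for differential-abundance null calibration, 20 for FDR
control, 1000–2000 reads for assignment conservation, full 720-way
enumeration for the exact-p check at n = 6. The whole suite runs in
well under a minute on one core.

## Known limitations

* The differential-abundance test has no dispersion shrinkage; with
  2–3 replicates its power is below a shrinkage-based NB GLM's, and
  published fold changes from such packages are not reproduced.
* PERMANOVA assumes exchangeable samples under the null (free
  permutation); restricted permutation schemes (strata) are not
  implemented.
* Ezekiel-adjusted fractions can be slightly negative and are not
  comparable across very different set ranks.
* The LCA taxonomy is held fully in memory — intended for taxonomies
  up to NCBI scale (~2.5 M nodes), not beyond.
* NMDS stress depends on restart count at difficult configurations;
  the defaults (PCoA start + 15 restarts) are conservative for n ≤ a
  few hundred samples.
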