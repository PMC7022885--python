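# rhizomine

Mining host-targeted RNA-seq for the taxonomic and functional diversity
of root-associated microbiota.

Plant RNA-seq experiments are sequenced to study the host, but a few
percent of the reads come from the microbes living on and in the roots.
`rhizomine` turns that discarded fraction into community ecology: it
assigns short non-host reads to taxa, makes them functionally
annotatable, builds and filters count tables, and asks how the
resulting community profiles relate to the experimental design and to
the host transcriptome. It is written for microbiome researchers who
have alignment outputs (BLAST-tabular hits against a taxid-annotated
reference) and want a tested, deterministic, scriptable path from reads
to statistics.

## What it computes

* **LCA read assignment** — per read, hits are filtered at ≥ 97%
  identity and restricted to best score; one surviving taxid is
  assigned directly ("nearest neighbor"), several are promoted to
  their lowest common ancestor on the NCBI-style taxonomy. Every read
  lands in exactly one bucket (a taxon or "unassigned").
* **Pseudo-reads** — each mapped 50 bp interval is extended 50 bp
  upstream and downstream along its reference (clipped at the ends)
  and extracted, giving 150 bp fragments long enough for protein-level
  orthology annotation. Redundant HSPs are de-duplicated per
  (read, subject) pair.
* **Count tables** — contaminant-lineage removal (Viridiplantae,
  Metazoa), the low-abundance rule (keep features with ≥ 5 raw reads
  in ≥ 3 libraries), family-level aggregation, and median-of-ratios
  size-factor normalization, plus a negative-binomial Wald
  differential-abundance test with Benjamini–Hochberg adjustment.
* **Community statistics** — Bray–Curtis distances
  (d = Σ|x−y| / Σ(x+y)); two-factor PERMANOVA with interaction
  (McArdle–Anderson partitioning, sequential SS, pseudo-F =
  MS_term/MS_residual, free-permutation p with 999 permutations);
  non-metric MDS (Kruskal stress-1); hypergeometric pathway
  over-representation of KO identifiers at p < 0.1.
* **Variance partitioning** — redundancy analysis with
  Ezekiel-adjusted R², forward selection (permutation tests plus the
  adjusted-R² ceiling), and inclusion–exclusion decomposition of host
  transcriptome variance into unique and shared fractions of up to
  four explanatory sets.
* **Mycorrhizal colonization** — the Trouvelot parameters F, M, m, a,
  A from per-segment microscopy classes.
* **Synthetic data** — seeded generators for every input format with
  recorded ground truth, so the whole pipeline is testable offline.

## Worked example

Given a published-style PERMANOVA table's degrees of freedom and sums
of squares, the derived columns (MS, pseudo-F, R², explained variance)
follow from the definitions and can be recomputed and checked:

```python
from rhizomine import finalize_permanova_table

table = finalize_permanova_table(
    {"Genotype": 1, "Soil": 2, "Genotype:Soil": 2, "Residual": 12},
    {"Genotype": 0.10739, "Soil": 0.05908,
     "Genotype:Soil": 0.0838, "Residual": 0.28391},
    ss_total=0.53421,
)
print(table.round(4).to_string())
```

```
               Df      SS      MS  pseudo_F      R2   p  explained_pct
Genotype        1  0.1074  0.1074    4.5390  0.2010 NaN        20.1026
Soil            2  0.0591  0.0295    1.2486  0.1106 NaN        11.0593
Genotype:Soil   2  0.0838  0.0419    1.7710  0.1569 NaN        15.6867
Residual       12  0.2839  0.0237       NaN  0.5315 NaN        53.1458
Total          17  0.5342     NaN       NaN  1.0000 NaN       100.0000
```

Reading: genotype explains 20.1% of the community-composition variance
(its SS over the total), and its mean square is 4.54 times the residual
mean square — the pseudo-F that the permutation test would referee
(p is NaN here because only the printed SS, not the distance matrix,
was supplied).

Colonization scoring works from raw segment classes:

```python
from rhizomine import SegmentScore, trouvelot

scores = ([SegmentScore(0)] * 30 + [SegmentScore(1, 1)] * 12
          + [SegmentScore(3, 2)] * 12 + [SegmentScore(5, 3)] * 6)
p = trouvelot(scores)
print(p)  # F=50.0, M=15.7, m=31.4, a=79.75, A=12.52
```

Half the segments are colonized (F = 50%), colonization intensity over
the whole root system is 15.7%, within colonized segments 31.4%, and
arbuscules account for 79.75% of that colonized intensity.

An end-to-end run on synthetic inputs (18 samples, per-sample hit
files) goes through the CLI:

```bash
rhizomine simulate --seed 7 --n-reads 400 --outdir sim/
rhizomine run --alignments sim/ --taxonomy sim/taxonomy.tsv \
    --metadata sim/metadata.tsv --seed 7 --outdir results/
```

`results/` then contains the raw, filtered, family-aggregated and
normalized count tables, size factors, the Bray–Curtis matrix, the
PERMANOVA table, NMDS coordinates with the achieved stress, and a
`summary.json` / `config.json` pair; every table carries a provenance
header (version, config hash, seed) and re-running with the same seed
reproduces every file byte for byte. Since the default simulation puts
the same community in every sample, the PERMANOVA terms come out null
(genotype p ≈ 0.73 at seed 7) — exactly what a calibrated test should
say there.

Each stage is also available as its own subcommand (`assign`,
`filter`, `aggregate`, `pseudoreads`, `normalize`, `diffabund`,
`permanova`, `nmds`, `enrich`, `varpart`, `trouvelot`), and everything
the CLI does is a thin call into the library.

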