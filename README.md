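# cnvpop

Population-genetic analysis of copy-number variation (CNV) in structured
populations: from per-individual CNV call sets to CNV regions, CNV genes,
per-individual gene copy-number genotypes, deletion-allele frequencies,
V<sub>ST</sub>/ANOVA differentiation scans, nonmetric MDS of population
structure, and genome-permutation nulls for interval–gene overlap — plus a
seeded synthetic-data generator so the whole pipeline is testable without
any external data.

## What it does

- **`cnvpop.model`** — domain types (intervals, calls, genes, segmental
  duplications, genome with assembly gaps, sample sheet), TSV readers and
  writers, and the call-level filters applied before any analysis
  (length ≥ 1 kb, zero overlap with assembly gaps). Coordinates are 0-based
  half-open (BED convention) throughout.
- **`cnvpop.regions`** — merge overlapping calls across individuals into CNV
  regions (CNVRs), presence spectra (how many individuals carry each CNVR),
  partition by segmental-duplication (SD > 10 kb) overlap, and
  Kolmogorov–Smirnov comparisons of call-length and log2 haploid
  copy-number distributions between the two partitions (absolute deletions
  floored at 0.001 before the log).
- **`cnvpop.genic`** — "CNV genes" via whole-gene containment in single
  calls, sex-aware baselines (male X is hemizygous, baseline 1),
  length-weighted average copy number per gene and individual, the
  genes × samples copy-number matrix, high-copy genes (mean CN ≥ 10), and
  hypergeometric enrichment of CNV genes in SDs.
- **`cnvpop.popdiff`** — V<sub>ST</sub> = (V<sub>T</sub> − V<sub>S</sub>)/V<sub>T</sub>
  with divisor-*n* variances and sample-size weighting; per-gene pairwise
  scans; deletion-allele frequencies from integer copy numbers with the
  hemizygous-X rules and the CN ≥ 3 lower-bound convention; one-way ANOVA →
  Benjamini–Hochberg FDR → ≥ 1-copy mean-difference filter → Tukey HSD scan;
  per-gene standardization; Kruskal nonmetric MDS on Euclidean
  inter-individual distances.
- **`cnvpop.permute`** — uniform re-placement of interval sets across the
  gap-free genome and upper-tail empirical p-values (plus-one corrected) for
  gene-overlap statistics.
- **`cnvpop.simulate`** — seeded generator of four unequal populations
  (8/8/8/3), autosomes + X with male hemizygosity, SD-associated large
  frequent duplications vs. small rare deletion-biased background calls,
  segregating Hardy–Weinberg whole-gene deletions, high-copy genes, and
  planted population mean shifts, all recorded in a truth table.

## Command line

Every stage is a subcommand of `cnvpop`; `all` chains them on a simulated
data set and is byte-identical across reruns with the same seed:

```sh
# full pipeline on the default synthetic data set
cnvpop all --out run1 --seed 17

# individual stages on your own TSV inputs
cnvpop simulate --out sim --seed 1
cnvpop filter   --calls-dir sim/calls --sample-sheet sim/samples.tsv \
                --chrom-sizes sim/chrom.sizes --gaps sim/gaps.tsv --out filtered
cnvpop cnvr     --calls-dir filtered --sample-sheet sim/samples.tsv \
                --sds sim/sds.tsv --out tables
cnvpop genes    --calls-dir filtered --sample-sheet sim/samples.tsv \
                --genes sim/genes.tsv --sds sim/sds.tsv --out tables
cnvpop genotype --calls-dir filtered --sample-sheet sim/samples.tsv \
                --cnv-genes tables/cnv_genes.tsv --out tables
cnvpop vst      --matrix tables/cn_matrix.tsv --sample-sheet sim/samples.tsv --out tables
cnvpop scan     --matrix tables/cn_matrix.tsv --sample-sheet sim/samples.tsv --out tables
cnvpop delfreq  --matrix tables/cn_matrix.tsv --sample-sheet sim/samples.tsv --out tables
cnvpop mds      --matrix tables/cn_matrix.tsv --out tables
cnvpop permute  --cnvrs tables/cnvrs.tsv --genes sim/genes.tsv \
                --chrom-sizes sim/chrom.sizes --gaps sim/gaps.tsv --out tables
```

Input formats: calls are TSV `chrom start end call_type cn` (one file per
sample, named `<sample_id>.tsv`); genes are BED4 with a gene id; SDs and
gaps are BED3; chromosome lengths use the two-column `chrom.sizes` layout;
the sample sheet is `sample_id population sex`. Thresholds (`--min-len`,
`--sd-min-len`, `--alpha`, `--min-mean-diff`, `--high-copy-threshold`,
`--n-perm`, …) are flags on every subcommand. Logs go to stderr and
`run.log`; tables only to files.

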