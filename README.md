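# methylkl

Depth-bias-corrected analysis of CpG methylation bimodality.

Per-site methylation levels (beta = methylated reads / total reads) from
whole-genome bisulfite sequencing show a bimodal distribution, but part of
that bimodality is an artifact of heterogeneous sequencing depth: shallow
sites can only take a few beta values, piling mass onto 0 and 1. `methylkl`
removes this bias by comparing the observed beta distribution against an
exact, depth-matched binomial null — an analytic mixture in which every
site keeps its real depth but its methylated-read count is binomial at the
sample's mean methylation level. The deviation of observed from null is
quantified with relative entropy: the endpoint terms KL(0) and KL(1)
(in bits) measure how strongly sites are conserved in the unmethylated and
methylated states, and are stratified by the flanking-sequence context of
each CpG (tetranucleotides N5-C-G-N3 and trinucleotides N5-C-G, with the
two DNA strands counted separately).

Key properties of the implementation:

- Beta values are exact reduced fractions; equal values merge across
  depths (1/2 from depth 2 and 2/4 from depth 4 are one support point),
  and all distributions are built in exact rational arithmetic, so they
  sum to 1 exactly and the null's mean equals p exactly.
- The null is computed analytically; Monte-Carlo sampling of the same null
  is provided only as a validation cross-check.
- A synthetic-data module generates references with planted CpGs and
  methylomes with context-dependent bimodal truth, heterogeneous depth and
  binomial read sampling, so the whole pipeline is testable offline.

## Command-line use

```sh
# analyze a Bismark-style cytosine/CX report against a FASTA reference
methylkl analyze --calls calls.cx.tsv --reference ref.fa --out results/ \
    --mode tetra --depths 4,6,8

# restrict to regions (e.g. partially methylated domains), BED 0-based
methylkl analyze --calls calls.cx.tsv --reference ref.fa \
    --regions pmds.bed --keep inside --out results_pmd/

# generate a synthetic reference + methylome (seeded, reproducible)
methylkl simulate --out sim/ --seed 1 --length 200000 --cpg-rate 0.02

# generate a binomial null methylome for a given depth profile
methylkl simulate --out null/ --null --depth-profile profile.tsv --p 0.5

# run the built-in analytic-vs-oracle self-checks
methylkl validate --seed 0
```

`analyze` writes the observed and null distribution tables, a whole-sample
summary row, per-context divergence tables (16 tetranucleotide or 4
trinucleotide rows: p, endpoint masses, KL(0), KL(1), d(0), d(1), full
KL), optional per-depth strata, and a JSON run manifest. Every output
file carries a `#`-comment header naming its inputs and filters.

Input formats: cytosine/CX reports (tab-separated: chrom, 1-based
position, strand, methylated count, unmethylated count, context class,
trinucleotide) or bedGraph coverage rows (`--format bedgraph`); FASTA
references; BED3+ region sets. Counts are always the source of truth —
percentage columns are recomputed and only warned about.

## Library layout

| module | contents |
| --- | --- |
| `methylkl.io` | CX / bedGraph / FASTA / BED readers, TSV writers, `MethylationSite`, `GenomicInterval` |
| `methylkl.context` | strand-aware tetranucleotide / trinucleotide context extraction, CpG enumeration |
| `methylkl.distributions` | exact beta distributions, depth profiles, binomial pmf, analytic + sampled null |
| `methylkl.divergence` | full KL, endpoint KL(0)/KL(1), direct differences, per-collection summaries |
| `methylkl.stratified` | per-context / per-depth / per-region analyses, mean-methylation tables |
| `methylkl.simulate` | reference and methylome simulators, null-methylome generator |
| `methylkl.cli` | `methylkl analyze / simulate / validate` |
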