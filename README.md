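# tacgvar

Annotation post-processing for GWAS variants in miRNA-targeted 3'UTRs.

Genome-wide association studies report thousands of trait-associated
variants, most of them non-coding. Variants sitting in a gene's 3'
untranslated region are of particular regulatory interest: miRNAs bind
3'UTRs to repress translation, so a 3'UTR variant can change miRNA binding
affinity and with it the gene's regulation. `tacgvar` is the batch tooling
for that analysis. Starting from ANNOVAR-style annotation tables for a
collection of traits (one table per trait, as produced when per-trait
miRNA-target variant lists are run through ANNOVAR), it:

- tallies each trait's variants over the 13 ANNOVAR region categories
  (intergenic, intronic, ncRNA_intronic, UTR3, exonic, downstream,
  upstream, ncRNA_exonic, UTR5, upstream;downstream, splicing,
  ncRNA_splicing, UTR5;UTR3);
- computes the per-trait **3'UTR prevalence**, the statistic used to rank
  traits by how strongly their target genes are hit in the 3'UTR:
  `prevalence = 100 · n(3'UTR occurrences) / n(unique genes)`, with either
  variant records or distinct 3'UTR-hit genes as the numerator;
- intersects variants and genes across traits and builds the all-pairs
  trait-by-trait overlap matrix (allele-aware or positional variant
  identity);
- projects MEME motif occurrences from 3'UTR sequence coordinates onto
  genomic coordinates (strand-aware, 1-based inclusive throughout) and
  reports every variant falling fully inside a projected motif region —
  candidate miRNA-binding disruptions;
- filters GTEx-style eQTL tables to per-tissue eGene sets under strict
  thresholds (Storey q < 0.05 and MAF > 0.05) and crosses them with trait
  gene lists into a gene-by-tissue presence matrix;
- scores gene-set enrichment over user-supplied GMT annotations with the
  hypergeometric upper tail or the conservative EASE variant
  (`P(X ≥ k−1)`), `fold = (k/n)/(K/N)`, Benjamini–Hochberg adjusted.

A deterministic fixture generator (`tacgvar simulate ...` /
`tacgvar.fixtures`) produces every input format with a JSON ledger of
planted ground truth, so the whole pipeline is testable offline.

## Worked example

Generate a small synthetic batch of trait files and summarize it:

```sh
$ tacgvar simulate traits --seed 5 --n-traits 6 --n-variants 30 --out traits
6 trait files written to traits
$ tacgvar prevalence --in traits --out run
6 traits summarized
$ head -3 run.prevalence.tsv
# tacgvar 0.1.0
trait   n_records  intergenic  intronic  ...  n_unique_genes  n_utr3_variants  n_utr3_genes  prevalence_pct  prevalence_rank
Trait01 30         6           14        ...  36              0                0             0.0             6
```

Each row is one trait: its record count, the 13 category tallies, the
number of distinct gene symbols in the file, the 3'UTR variant and gene
counts, and the prevalence percentage with its rank across the batch
(Trait01 here has no 3'UTR variants, hence 0.0 and last rank). Gene
overlap between two traits:

```sh
$ tacgvar common-genes traits/Trait01.genes.txt traits/Trait02.genes.txt
# tacgvar 0.1.0
GENE0043
GENE0160
# shared: 2
```

`tacgvar run-all --in DIR --out PREFIX` runs every stage over a directory
and writes the prevalence table, both overlap matrices (and per-trait
nonzero-partner counts), and — when `--meme/--utr/--eqtl` inputs are
supplied — the motif-hit table and per-tissue eGene sets, as TSV/JSON with
the effective configuration saved alongside.

As a library: `tacgvar.io_annovar` (parsing/normalization),
`tacgvar.trait_stats`, `tacgvar.cross_trait`, `tacgvar.motif_map`,
`tacgvar.enrich_eqtl`, `tacgvar.fixtures`, and `tacgvar.datasets`
(bundled published reference inputs such as the child-obesity target-gene
table and the two worked motif-hit examples).

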