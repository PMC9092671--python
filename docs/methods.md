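# Methods

## Data model and conventions

All genomic coordinates are 1-based inclusive, the ANNOVAR convention; BED
input is converted at the boundary (`--bed`, start+1). Chromosome labels
are compared after stripping a `chr` prefix, so mixed-source trait files
(`chr6` vs `6`) intersect correctly. Region categories are folded onto the
fixed 13-token vocabulary case-insensitively, with the `3'UTR`/`5'UTR`
spellings mapped to `UTR3`/`UTR5`; a token outside the vocabulary never
aborts a run — the row is excluded and tallied under `unclassified`,
because exported "ANNOVAR-formatted" files drift in dialect. Rows with
non-numeric coordinates or start > end are collected as row errors and
reported; accepted + unclassified + errored always equals the file's data
rows. Gene fields are split on commas/semicolons with `(dist=…)` suffixes
stripped; the `NONE` placeholder yields an empty gene set. Column positions
are configurable by header name or 0-based index because no canonical
header exists for these exports; the default map is ANNOVAR's
`variant_function` layout.

## 3'UTR prevalence

For one trait, `prevalence_pct = 100 · numerator / n_unique_genes`, where
the denominator is the count of distinct gene symbols across *all*
categories in the trait file, not only 3'UTR-bearing genes. The numerator
is selectable: 3'UTR variant records (`variants`, the default) or distinct
genes with ≥ 1 3'UTR variant (`genes`). The default follows the reading of
the statistic as a percentage of 3'UTR *variants*; both modes coincide when
each 3'UTR gene carries exactly one 3'UTR variant (as in the 12-of-16
configuration that yields 75%), which is why both are shipped and the mode
is recorded in every output. In variants mode the statistic exceeds 100
whenever genes carry multiple 3'UTR variants; that is legal and tested. A
trait file with no gene symbols at all has an undefined prevalence and is a
hard error, never a silent zero. Table output rounds half-even to one
decimal; the JSON mirror keeps full precision.

## Cross-trait overlap

Overlap is a set notion: each trait's variants are deduplicated under the
chosen identity before any counting, so repeated rows in one file cannot
inflate a pairwise count. Two identities are provided because published
overlap counts rarely state their rule: `full` (chrom, start, end, ref,
alt — the default) and `positional` (locus only). Sets built under
different identities refuse to intersect. The all-pairs matrix is
symmetric with each trait's set size on the diagonal; a per-trait
"nonzero partners" summary counts other traits sharing ≥ 1 item
(threshold 1 being the plain reading of "has overlaps with"). Matrices are
written square and long-form.

## Motif-region mapping

MEME reports sites relative to its input sequences; here those are 3'UTR
sequences extracted in the gene's orientation. The projection contract,
with `L` the UTR length and site `[s, e]` (1-based inclusive within the
oriented sequence):

- `+` strand: `[g_start + s − 1, g_start + e − 1]`
- `−` strand: `[g_end − e + 1, g_end − s + 1]`

This makes the projection an involution-tested bijection (round-trip
property on both strands) and gives strand-flip symmetry: reindexing a
site through reverse complementation (`s,e → L−e+1, L−s+1`) with the
opposite strand lands on the same genomic interval. MEME XML positions are
0-based and converted on parse; already-genomic intervals can bypass the
projection entirely (pre-mapped `MappedMotif` inputs).

A variant is a motif hit when its whole `[start, end]` lies inside the
projected interval, endpoints inclusive. The strict full-containment rule
only matters for multi-base variants — single-base substitutions are
unaffected — and is the conservative choice for deletions straddling a
motif edge. Matching is chromosome-scoped, and additionally gene-scoped
whenever both the variant and the occurrence carry gene labels, preventing
spurious pairings at coincident coordinates across genes. The scan uses a
per-chromosome interval tree; its results are required (by test) to equal
a brute-force enumeration of every covered genomic position.

## eQTL filtering and enrichment

eGene filtering applies strict inequalities — q < q_max and MAF > maf_min,
defaults 0.05/0.05 — taken literally from the thresholds' usual statement;
boundary rows (exactly 0.05) are excluded, and the fixture generator plants
such rows deliberately. Ensembl version suffixes are stripped before
deduplication. Relaxing either threshold can only grow an eGene set
(tested monotonicity). Study-gene/eGene overlap reports a gene-by-tissue
boolean matrix plus per-tissue counts; study genes without an identifier
mapping are scored "no" with a warning, never dropped silently, since a
missing mapping is information.

Enrichment is plain arithmetic over caller-supplied GMT annotations with
the caller's background (all annotated genes is the conventional choice):
`fold = (k/n)/(K/N)`, upper-tail hypergeometric `P(X ≥ k)` via
`scipy.stats.hypergeom`, and the EASE score `P(X ≥ k−1)` — one success
removed, DAVID's conservative variant, always ≥ the plain tail — with
Benjamini–Hochberg adjustment across terms (statsmodels). Term gene sets
are trimmed to the background with a warning; terms with no background
genes are dropped. No term database or web-service correction method is
bundled: curated-database content and service-side algorithms are not
reproducible arithmetic, whereas the tail probabilities are.

## Synthetic-data generators

The generators exist so every pipeline input has an offline, seeded,
ledgered counterpart; a single integer seed drives one `numpy` Generator
stream and regeneration is byte-identical.

- **Trait files**: default 31 traits of 100 variants over a shared
  400-gene pool, with a category mix shaped like typical GWAS annotation
  output (intron/intergenic heavy, 8% UTR3, rare splicing/compound
  tokens). Pairwise shared variants are planted exactly per an overlap
  spec at globally unique loci, so realized overlaps equal the spec by
  construction. Files include mixed-case tokens, the `3'UTR` spelling and
  `(dist=…)` gene fields to exercise normalization. A full-coverage option
  deals the whole gene pool across records, pinning the unique-gene
  denominator (used for the 12-of-16 → 75% configuration).
- **UTR/motif fixture**: per gene one planted site of a common consensus,
  alternating strands; the ledger stores the site in sequence *and*
  genomic coordinates, the latter computed by projection arithmetic local
  to the generator, independent of the module under test. Planted
  inside/outside variants are verified against a brute-force containment
  check before writing.
- **eQTL table**: per tissue a planted eGene fraction (default 35% of 200
  genes, two tissues); eGenes get ≥ 1 passing row, non-eGenes only failing
  rows, including exact-boundary rows.

What the fixtures do **not** model: linkage disequilibrium, realistic
allele-frequency spectra, sequence composition, or biologically meaningful
gene symbols. Passing tests therefore demonstrate the correctness of the
counting, set, coordinate and filtering logic on well-formed and mildly
messy inputs — not robustness to every wild export dialect, and not any
biological claim.

## Problem sizes and reference checks

The test suite and acceptance script run on desk-scale inputs chosen to
keep the full offline run in seconds: 31-trait batches of 20–40 variants,
motif fixtures of 4–8 genes, 200-gene eQTL tables, ledger-fidelity sweeps
over 20 seeds, and exhaustive hypergeometric enumeration up to N = 12.
Published reference inputs bundled in `tacgvar.datasets` (the
child-obesity gene-by-tissue eGene table, the two worked motif-hit
coordinate examples, the four-gene blood-trait intersection) are checked
end-to-end through the same code paths. For the DNA-binding fold check,
the original report's background sizes are not published; the bundled
check uses K = 79 annotated genes in an N = 846 background, the smallest
integer pair consistent with the reported fold at k = 5, n = 16, and
verifies the arithmetic to ~1e-5 relative. The EASE p-value reported by
the acceptance script is computed under that same reconstructed
background, so it checks the tail arithmetic rather than any particular
curated database.

## Known limitations

- ANNOVAR itself is consumed, not run: no annotation engine, no genome
  build liftover, no VCF ingestion.
- Motif discovery is consumed, not run: no EM, no PWM rescanning, no
  miRNA seed-match prediction.
- No significance testing of cross-trait overlaps and no eQTL mapping;
  these are upstream or out of scope.
- Header auto-detection keys on a numeric start field; a headerless file
  whose first row has malformed coordinates should be parsed with
  `has_header=False`.
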