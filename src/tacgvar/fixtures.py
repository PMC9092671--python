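"""Deterministic synthetic-data generators with a ground-truth ledger.

Every input format the pipeline consumes can be generated offline: batches
of ANNOVAR-style trait files with planted category mixes and pairwise
shared variants, 3'UTR sequence/interval/MEME fixtures with motif sites
planted at known positions on both strands, and GTEx-style eQTL pair tables
with planted eGene sets and deliberate threshold-boundary rows.

Each generator records every planted fact in a :class:`FixtureLedger`
written as JSON next to the data, so tests can re-derive the facts through
the pipeline's own readers and compare.  A single integer seed drives all
randomness through one ``numpy`` generator stream; regeneration with the
same seed is byte-identical.

The fixtures deliberately mimic the messiness of real exports: occasional
mixed-case category tokens, the ``3'UTR`` spelling, and intergenic gene
fields with ``(dist=...)`` suffixes, so normalization is exercised.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io_annovar import REGION_CATEGORIES
from .motif_map import Utr3Interval, write_utr_table

LEDGER_NAME = "fixture_ledger.json"

#: Default region-category mix for generated trait files: intron/intergenic
#: heavy with a modest 3'UTR fraction, the typical shape of GWAS annotation
#: output.
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "intronic": 0.45,
    "intergenic": 0.25,
    "UTR3": 0.08,
    "exonic": 0.05,
    "downstream": 0.04,
    "upstream": 0.04,
    "ncRNA_intronic": 0.04,
    "UTR5": 0.02,
    "ncRNA_exonic": 0.015,
    "splicing": 0.005,
    "upstream;downstream": 0.005,
    "ncRNA_splicing": 0.003,
    "UTR5;UTR3": 0.002,
}

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureLedger:
    """Machine-readable record of everything a generator planted.

    Only the sections relevant to the generator that produced it are
    populated; the rest stay empty.
    """

    seed: int
    trait_category_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    trait_n_variants: dict[str, int] = field(default_factory=dict)
    trait_genes: dict[str, list[str]] = field(default_factory=dict)
    pairwise_shared_variants: dict[str, int] = field(default_factory=dict)
    motif_sites: dict[str, dict] = field(default_factory=dict)
    variants_in_motifs: list[dict] = field(default_factory=list)
    variants_outside_motifs: list[dict] = field(default_factory=list)
    egenes: dict[str, list[str]] = field(default_factory=dict)

    @staticmethod
    def pair_key(a: str, b: str) -> str:
        return "|".join(sorted((a, b)))

    def write(self, out_dir: Union[str, Path]) -> Path:
        path = Path(out_dir) / LEDGER_NAME
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def read(cls, out_dir: Union[str, Path]) -> "FixtureLedger":
        payload = json.loads((Path(out_dir) / LEDGER_NAME).read_text())
        return cls(**payload)


def _random_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i, j = rng.choice(4, size=2, replace=False)
    return str(_BASES[i]), str(_BASES[j])


def _style_category(rng: np.random.Generator, category: str) -> str:
    """Occasionally roughen the category spelling to exercise normalization."""
    roll = rng.random()
    if roll < 0.05 and category == "UTR3":
        return "3'UTR"
    if roll < 0.10:
        return category.upper()
    if roll < 0.15:
        return category.lower()
    return category


class _LocusCounter:
    """Strictly increasing genomic positions so every generated locus is unique
    unless deliberately shared."""

    def __init__(self, rng: np.random.Generator, start: int = 1_000_000) -> None:
        self._rng = rng
        self._pos = start
        self._i = 0

    def next(self) -> tuple[str, int]:
        self._pos += int(self._rng.integers(50, 500))
        chrom = str(self._i % 22 + 1)
        self._i += 1
        return chrom, self._pos


def _draw_categories(
    rng: np.random.Generator, n: int, mix: Mapping[str, float]
) -> list[str]:
    tokens = list(mix)
    probs = np.array([mix[t] for t in tokens], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"category mix sums to {probs.sum()}, not 1")
    if any(t not in REGION_CATEGORIES for t in tokens):
        bad = [t for t in tokens if t not in REGION_CATEGORIES]
        raise ValueError(f"category mix contains unknown tokens {bad}")
    return [tokens[i] for i in rng.choice(len(tokens), size=n, p=probs)]


def gen_trait_files(
    out_dir: Union[str, Path],
    n_traits: int = 31,
    n_variants: int = 100,
    category_mix: Mapping[str, float] | None = None,
    overlap_spec: Mapping[tuple[str, str], int] | None = None,
    gene_pool_size: int = 400,
    seed: int = 0,
    exact_category_counts: Mapping[str, int] | None = None,
    full_gene_coverage: bool = False,
    dialect: str = "tsv",
) -> FixtureLedger:
    """Generate a directory of ANNOVAR-style trait files with known truth.

    Each trait receives ``n_variants`` private variants (categories drawn
    from ``category_mix``, or laid out exactly by ``exact_category_counts``)
    at globally unique loci, plus the shared variants requested by
    ``overlap_spec`` — a mapping ``(trait_a, trait_b) -> count`` planting
    exactly that many variants present in both files and nowhere else, so
    realized pairwise overlaps equal the spec.  A gene-list ``.txt`` file
    accompanies each trait.  With ``full_gene_coverage`` every pool gene is
    dealt to at least one variant of every trait (extra genes are appended
    to early records), which pins the unique-gene denominator at the pool
    size.

    An infeasible spec (unknown trait names, negative counts, a mix not
    summing to 1) raises before any file is written.  Returns the ledger,
    also written as JSON into ``out_dir``.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    mix = dict(category_mix) if category_mix is not None else dict(DEFAULT_CATEGORY_MIX)
    trait_ids = [f"Trait{i + 1:02d}" for i in range(n_traits)]
    overlap_spec = dict(overlap_spec or {})

    # Validate everything before touching the filesystem.
    if exact_category_counts is not None:
        bad = [t for t in exact_category_counts if t not in REGION_CATEGORIES]
        if bad:
            raise ValueError(f"exact_category_counts has unknown tokens {bad}")
        if sum(exact_category_counts.values()) != n_variants:
            raise ValueError("exact_category_counts must sum to n_variants")
    else:
        _draw_categories(rng, 0, mix)  # validates the mix
    known = set(trait_ids)
    for (a, b), count in overlap_spec.items():
        if a not in known or b not in known or a == b:
            raise ValueError(f"overlap_spec pair ({a}, {b}) is not a valid trait pair")
        if count < 0:
            raise ValueError(f"overlap_spec count for ({a}, {b}) is negative")

    out_dir.mkdir(parents=True, exist_ok=True)
    pool = [f"GENE{i + 1:04d}" for i in range(gene_pool_size)]
    locus = _LocusCounter(rng)
    ledger = FixtureLedger(seed=seed)

    rows: dict[str, list[list[str]]] = {t: [] for t in trait_ids}
    genes_seen: dict[str, set[str]] = {t: set() for t in trait_ids}
    counts: dict[str, dict[str, int]] = {
        t: {tok: 0 for tok in REGION_CATEGORIES} for t in trait_ids
    }

    def make_row(trait: str, category: str, gene_syms: list[str]) -> list[str]:
        chrom, pos = locus.next()
        ref, alt = _random_alleles(rng)
        if category == "intergenic" and len(gene_syms) >= 2 and rng.random() < 0.6:
            d1, d2 = rng.integers(100, 5000, size=2)
            gene_field = f"{gene_syms[0]}(dist={d1}),{gene_syms[1]}(dist={d2})"
        else:
            gene_field = ",".join(gene_syms)
        counts[trait][category] += 1
        genes_seen[trait].update(gene_syms)
        return [_style_category(rng, category), gene_field, chrom,
                str(pos), str(pos), ref, alt]

    # planted shared variants: one unique locus per shared record, written
    # verbatim into both trait files
    for (a, b), count in sorted(overlap_spec.items()):
        ledger.pairwise_shared_variants[FixtureLedger.pair_key(a, b)] = count
        for _ in range(count):
            chrom, pos = locus.next()
            ref, alt = _random_alleles(rng)
            category = (
                _draw_categories(rng, 1, mix)[0]
                if exact_category_counts is None
                else "UTR3"
            )
            gene = pool[int(rng.integers(len(pool)))]
            row = [category, gene, chrom, str(pos), str(pos), ref, alt]
            for t in (a, b):
                rows[t].append(list(row))
                counts[t][category] += 1
                genes_seen[t].add(gene)

    # private variants per trait
    for trait in trait_ids:
        if exact_category_counts is not None:
            cats: list[str] = []
            for tok, c in exact_category_counts.items():
                cats.extend([tok] * c)
            rng.shuffle(cats)
        else:
            cats = _draw_categories(rng, n_variants, mix)
        if full_gene_coverage:
            dealt = list(pool)
            rng.shuffle(dealt)
            per_variant: list[list[str]] = [[] for _ in range(len(cats))]
            for i, g in enumerate(dealt):
                per_variant[i % len(cats)].append(g)
            for syms in per_variant:  # pool smaller than n_variants
                if not syms:
                    syms.append(pool[int(rng.integers(len(pool)))])
        else:
            per_variant = [
                [pool[int(j)] for j in rng.choice(len(pool), size=2, replace=False)]
                for _ in cats
            ]
            per_variant = [
                syms if cats[i] == "intergenic" else syms[:1]
                for i, syms in enumerate(per_variant)
            ]
        for cat, syms in zip(cats, per_variant):
            rows[trait].append(make_row(trait, cat, syms))

    delim = "\t" if dialect == "tsv" else ","
    ext = "tsv" if dialect == "tsv" else "csv"
    for trait in trait_ids:
        with open(out_dir / f"{trait}.variant_function.{ext}", "w") as fh:
            w = csv.writer(fh, delimiter=delim, lineterminator="\n")
            w.writerows(rows[trait])
        (out_dir / f"{trait}.genes.txt").write_text(
            "\n".join(sorted(genes_seen[trait])) + "\n"
        )
        ledger.trait_category_counts[trait] = counts[trait]
        ledger.trait_n_variants[trait] = len(rows[trait])
        ledger.trait_genes[trait] = sorted(genes_seen[trait])

    ledger.write(out_dir)
    return ledger


# ---------------------------------------------------------------------------
# 3'UTR / motif fixture


def _project(seq_start: int, seq_end: int, g_start: int, g_end: int,
             strand: str) -> tuple[int, int]:
    # kept local and written out independently of motif_map so the ledger's
    # genomic coordinates are an independent oracle for the projection code
    if strand == "+":
        return g_start + seq_start - 1, g_start + seq_end - 1
    return g_end - seq_end + 1, g_end - seq_start + 1


def _write_meme_xml(
    path: Path,
    genes: Sequence[str],
    lengths: Mapping[str, int],
    motif_id: str,
    motif_width: int,
    consensus: str,
    sites: Mapping[str, tuple[int, int]],
) -> None:
    """Emit a minimal MEME-style XML document (0-based site positions)."""
    lines = ['<?xml version="1.0"?>', '<MEME version="5.4.1">', "  <training_set>"]
    seq_ids = {}
    for i, g in enumerate(genes):
        seq_ids[g] = f"sequence_{i}"
        lines.append(
            f'    <sequence id="sequence_{i}" name="{g}" length="{lengths[g]}"/>'
        )
    lines += [
        "  </training_set>",
        "  <motifs>",
        f'    <motif id="motif_1" name="{motif_id}" width="{motif_width}">',
        "      <contributing_sites>",
    ]
    for g in genes:
        if g not in sites:
            continue
        seq_start, _ = sites[g]
        lines.append(
            f'        <contributing_site sequence_id="{seq_ids[g]}" '
            f'position="{seq_start - 1}" strand="plus" pvalue="1e-8">'
        )
        lines.append("          <site>")
        for base in consensus:
            lines.append(f'            <letter_ref letter_id="{base}"/>')
        lines += ["          </site>", "        </contributing_site>"]
    lines += ["      </contributing_sites>", "    </motif>", "  </motifs>", "</MEME>", ""]
    path.write_text("\n".join(lines))


def gen_utr_motif_fixture(
    out_dir: Union[str, Path],
    n_genes: int = 8,
    utr_length_range: tuple[int, int] = (80, 300),
    motif_width: int = 20,
    strands: Sequence[str] = ("+", "-"),
    n_variants_in: int = 5,
    n_variants_out: int = 10,
    seed: int = 0,
) -> FixtureLedger:
    """Generate a 3'UTR motif fixture: FASTA, interval table, MEME output
    (XML and TSV) and a variant table with exactly ``n_variants_in`` variants
    planted inside projected motif intervals and ``n_variants_out`` outside.

    Each gene gets one planted motif site; strands alternate through
    ``strands``.  The ledger records every site in both sequence and genomic
    coordinates (the genomic side computed independently of the projection
    code under test) plus every planted variant, and the inside/outside
    counts are verified by a brute-force containment check before writing.
    """
    lo, hi = utr_length_range
    if motif_width > lo:
        raise ValueError("motif_width exceeds the minimum UTR length")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    genes = [f"UTRGENE{i + 1:02d}" for i in range(n_genes)]
    consensus = "".join(rng.choice(list("ACGT"), size=motif_width))
    motif_id = "MOTIF_A"

    utrs: dict[str, Utr3Interval] = {}
    seqs: dict[str, str] = {}
    sites_seq: dict[str, tuple[int, int]] = {}
    sites_gen: dict[str, tuple[int, int]] = {}
    g_cursor = 5_000_000
    for i, gene in enumerate(genes):
        length = int(rng.integers(lo, hi + 1))
        strand = strands[i % len(strands)]
        chrom = str(i % 22 + 1)
        g_start = g_cursor
        g_cursor += length + int(rng.integers(1_000, 10_000))
        utr = Utr3Interval(gene_id=gene, chrom=chrom, g_start=g_start,
                           g_end=g_start + length - 1, strand=strand)
        seq = list(rng.choice(list("ACGT"), size=length))
        seq_start = int(rng.integers(1, length - motif_width + 2))
        seq_end = seq_start + motif_width - 1
        seq[seq_start - 1: seq_end] = list(consensus)
        utrs[gene] = utr
        seqs[gene] = "".join(seq)
        sites_seq[gene] = (seq_start, seq_end)
        sites_gen[gene] = _project(seq_start, seq_end, utr.g_start, utr.g_end, strand)

    # plant variants: inside positions uniform within the site's genomic
    # interval, outside positions within the UTR but clear of the site
    inside: list[dict] = []
    outside: list[dict] = []
    for j in range(n_variants_in):
        gene = genes[j % n_genes]
        gs, ge = sites_gen[gene]
        pos = int(rng.integers(gs, ge + 1))
        ref, alt = _random_alleles(rng)
        inside.append({"gene": gene, "chrom": utrs[gene].chrom, "pos": pos,
                       "ref": ref, "alt": alt})
    for j in range(n_variants_out):
        gene = genes[j % n_genes]
        utr = utrs[gene]
        gs, ge = sites_gen[gene]
        candidates = [p for p in range(utr.g_start, utr.g_end + 1) if not gs <= p <= ge]
        if not candidates:
            raise ValueError(f"{gene}: motif covers the whole UTR; "
                             "cannot place an outside variant")
        pos = int(candidates[int(rng.integers(len(candidates)))])
        ref, alt = _random_alleles(rng)
        outside.append({"gene": gene, "chrom": utr.chrom, "pos": pos,
                        "ref": ref, "alt": alt})

    # brute-force verification of the planted containment facts
    def contained(rec: dict) -> bool:
        gs, ge = sites_gen[rec["gene"]]
        return gs <= rec["pos"] <= ge

    assert all(contained(r) for r in inside)
    assert not any(contained(r) for r in outside)

    out_dir.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seqs[g]), id=g, description=f"3'UTR {utrs[g].chrom}:"
                  f"{utrs[g].g_start}-{utrs[g].g_end}({utrs[g].strand})")
        for g in genes
    ]
    SeqIO.write(records, out_dir / "utr_sequences.fasta", "fasta")
    write_utr_table([utrs[g] for g in genes], out_dir / "utr_intervals.tsv")

    with open(out_dir / "meme_sites.tsv", "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sequence_id", "motif_id", "start", "end", "site", "score"])
        for g in genes:
            s, e = sites_seq[g]
            w.writerow([g, motif_id, s, e, consensus, "1.0"])
    _write_meme_xml(
        out_dir / "meme_output.xml", genes,
        {g: len(seqs[g]) for g in genes},
        motif_id, motif_width, consensus, sites_seq,
    )

    with open(out_dir / "variants.variant_function.tsv", "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for rec in inside + outside:
            w.writerow(["UTR3", rec["gene"], rec["chrom"],
                        rec["pos"], rec["pos"], rec["ref"], rec["alt"]])

    ledger = FixtureLedger(seed=seed)
    for g in genes:
        s, e = sites_seq[g]
        gs, ge = sites_gen[g]
        ledger.motif_sites[g] = {
            "motif_id": motif_id, "seq_start": s, "seq_end": e,
            "chrom": utrs[g].chrom, "g_start": gs, "g_end": ge,
            "strand": utrs[g].strand, "utr_g_start": utrs[g].g_start,
            "utr_g_end": utrs[g].g_end,
        }
    ledger.variants_in_motifs = inside
    ledger.variants_outside_motifs = outside
    ledger.write(out_dir)
    return ledger


# ---------------------------------------------------------------------------
# eQTL fixture


def gen_eqtl_table(
    out_dir: Union[str, Path],
    n_genes: int = 200,
    n_tissues: int = 2,
    frac_egenes: float = 0.35,
    seed: int = 0,
    tissue_names: Sequence[str] | None = None,
) -> FixtureLedger:
    """Generate a GTEx-style eQTL pair table with planted per-tissue eGenes.

    For each tissue, ``round(frac_egenes * n_genes)`` genes are planted as
    eGenes and receive at least one row passing the strict q < 0.05 /
    MAF > 0.05 filter; every other gene only receives failing rows.  Rows
    sitting exactly on both thresholds (q = 0.05 or MAF = 0.05) are planted
    deliberately so the strict-inequality contract is exercised.  Gene ids
    carry Ensembl-style version suffixes; the ledger stores versionless ids.
    """
    if not (0.0 <= frac_egenes <= 1.0):
        raise ValueError("frac_egenes must be within [0, 1]")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    tissues = list(tissue_names) if tissue_names else [
        f"Tissue_{i + 1:02d}" for i in range(n_tissues)
    ]
    base_ids = [f"ENSG{i + 1:011d}" for i in range(n_genes)]
    versions = {g: int(rng.integers(1, 15)) for g in base_ids}

    out_dir.mkdir(parents=True, exist_ok=True)
    ledger = FixtureLedger(seed=seed)
    rows: list[list[str]] = []
    n_e = round(frac_egenes * n_genes)
    for tissue in tissues:
        chosen = sorted(
            base_ids[i] for i in rng.choice(n_genes, size=n_e, replace=False)
        )
        ledger.egenes[tissue] = chosen
        chosen_set = set(chosen)
        for g in base_ids:
            gid = f"{g}.{versions[g]}"
            chrom = int(rng.integers(1, 23))
            pos = int(rng.integers(1_000_000, 50_000_000))
            vid = f"chr{chrom}_{pos}_A_G_b38"
            if g in chosen_set:
                q = float(rng.uniform(1e-6, 0.049))
                maf = float(rng.uniform(0.051, 0.5))
                rows.append([gid, vid, tissue, f"{q:.6g}", f"{maf:.6g}"])
                if rng.random() < 0.3:  # extra sub-threshold row for the same eGene
                    rows.append([gid, f"chr{chrom}_{pos + 17}_C_T_b38", tissue,
                                 f"{rng.uniform(0.05, 1.0):.6g}",
                                 f"{rng.uniform(0.051, 0.5):.6g}"])
            else:
                roll = rng.random()
                if roll < 0.15:  # exact q boundary, passing MAF
                    q, maf = 0.05, float(rng.uniform(0.051, 0.5))
                elif roll < 0.3:  # exact MAF boundary, passing q
                    q, maf = float(rng.uniform(1e-6, 0.049)), 0.05
                elif roll < 0.65:  # failing q
                    q, maf = float(rng.uniform(0.05, 1.0)), float(rng.uniform(0.051, 0.5))
                else:  # failing MAF
                    q, maf = float(rng.uniform(1e-6, 0.049)), float(rng.uniform(0.001, 0.05))
                rows.append([gid, vid, tissue, f"{q:.6g}", f"{maf:.6g}"])

    with open(out_dir / "eqtl_pairs.tsv", "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "variant_id", "tissue", "qval", "maf"])
        w.writerows(rows)
    ledger.write(out_dir)
    return ledger
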