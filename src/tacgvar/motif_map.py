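"""MEME motif occurrences: parsing, genome projection and variant containment.

MEME reports motif sites with coordinates relative to the input sequences —
here, 3'UTR sequences extracted in the orientation of the gene.  To compare
sites with ANNOVAR variant positions the site must be projected onto the
genome through the UTR's genomic interval and strand:

    + strand:  [g_start + seq_start - 1,  g_start + seq_end - 1]
    - strand:  [g_end - seq_end + 1,      g_end - seq_start + 1]

All coordinates on both sides are 1-based inclusive.  A variant is a hit
when its whole [start, end] interval lies inside a projected motif interval
on the same chromosome (and, when both sides carry gene labels, the same
gene) — endpoints inclusive, so a single-base variant at either motif edge
counts.
"""

from __future__ import annotations

import csv
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from intervaltree import IntervalTree

from .io_annovar import AnnotatedVariant, normalize_chrom

log = logging.getLogger(__name__)


class MemeParseError(ValueError):
    """Raised for malformed MEME output, naming the offending element or line."""


@dataclass(frozen=True)
class Utr3Interval:
    """A gene's 3'UTR as a genomic interval (1-based inclusive) with strand."""

    gene_id: str
    chrom: str
    g_start: int
    g_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.g_start > self.g_end:
            raise ValueError(f"{self.gene_id}: g_start > g_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def seq_length(self) -> int:
        return self.g_end - self.g_start + 1


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif site, positioned within the oriented 3'UTR sequence."""

    gene_id: str
    motif_id: str
    seq_start: int  # 1-based inclusive
    seq_end: int  # 1-based inclusive
    matched_site: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.seq_start <= self.seq_end):
            raise ValueError(
                f"{self.gene_id}/{self.motif_id}: bad site coords "
                f"{self.seq_start}-{self.seq_end}"
            )

    @property
    def width(self) -> int:
        return self.seq_end - self.seq_start + 1


@dataclass(frozen=True)
class MappedMotif:
    """A motif occurrence projected onto the genome (1-based inclusive)."""

    gene_id: str
    motif_id: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class MotifHit:
    """A variant falling fully inside a projected motif interval."""

    variant: AnnotatedVariant
    gene_id: str
    motif_id: str
    chrom: str
    motif_start: int
    motif_end: int

    @property
    def offset_in_motif(self) -> int:
        return self.variant.start - self.motif_start


# ---------------------------------------------------------------------------
# MEME output parsing


def parse_meme_tsv(path: Union[str, Path]) -> list[MotifOccurrence]:
    """Parse the simplified occurrence TSV.

    Columns (header required): sequence_id, motif_id, start, end and
    optionally site, score.  Coordinates are 1-based inclusive.
    """
    path = Path(path)
    occs: list[MotifOccurrence] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sequence_id", "motif_id", "start", "end"}
        if reader.fieldnames is None:
            return []
        missing = required - set(reader.fieldnames)
        if missing:
            raise MemeParseError(f"{path.name}: missing columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            try:
                occs.append(
                    MotifOccurrence(
                        gene_id=row["sequence_id"].strip(),
                        motif_id=row["motif_id"].strip(),
                        seq_start=int(row["start"]),
                        seq_end=int(row["end"]),
                        matched_site=(row.get("site") or None),
                        score=float(row["score"]) if row.get("score") else None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise MemeParseError(f"{path.name} line {line_no}: {exc}") from exc
    return occs


def parse_meme_xml(path: Union[str, Path]) -> list[MotifOccurrence]:
    """Parse MEME XML output into occurrences.

    Reads the training-set sequence table to map internal sequence ids back
    to sequence names, then collects each motif's contributing sites.  MEME
    reports site positions 0-based; they are converted to 1-based inclusive.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise MemeParseError(f"{path.name}: not well-formed XML ({exc})") from exc

    seq_names: dict[str, str] = {}
    for seq in root.iter("sequence"):
        sid, name = seq.get("id"), seq.get("name")
        if sid is None or name is None:
            raise MemeParseError(
                f"{path.name}: <sequence> element missing id/name attribute"
            )
        seq_names[sid] = name

    occs: list[MotifOccurrence] = []
    for motif in root.iter("motif"):
        motif_name = motif.get("name") or motif.get("id")
        width_attr = motif.get("width")
        if motif_name is None or width_attr is None:
            raise MemeParseError(f"{path.name}: <motif> element missing name/width")
        width = int(width_attr)
        for site in motif.iter("contributing_site"):
            sid = site.get("sequence_id")
            pos = site.get("position")
            if sid is None or pos is None:
                raise MemeParseError(
                    f"{path.name}: <contributing_site> missing sequence_id/position"
                )
            if sid not in seq_names:
                raise MemeParseError(
                    f"{path.name}: contributing_site references unknown sequence {sid!r}"
                )
            start = int(pos) + 1
            letters = [lr.get("letter_id", "") for lr in site.iter("letter_ref")]
            occs.append(
                MotifOccurrence(
                    gene_id=seq_names[sid],
                    motif_id=motif_name,
                    seq_start=start,
                    seq_end=start + width - 1,
                    matched_site="".join(letters) or None,
                )
            )
    return occs


def parse_meme(path: Union[str, Path], dialect: str = "auto") -> list[MotifOccurrence]:
    """Parse MEME output, auto-detecting XML vs simplified TSV."""
    path = Path(path)
    if dialect == "auto":
        head = path.read_text()[:200].lstrip()
        dialect = "xml" if head.startswith("<") else "tsv"
    if dialect == "xml":
        return parse_meme_xml(path)
    if dialect == "tsv":
        return parse_meme_tsv(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Coordinate projection


def map_to_genome(occ: MotifOccurrence, utr: Utr3Interval) -> MappedMotif:
    """Project a sequence-relative occurrence onto the genome.

    The occurrence must belong to the UTR's gene and fit inside its length.
    On the minus strand the oriented sequence runs from g_end toward
    g_start, so the projection reflects the coordinates.
    """
    if occ.gene_id != utr.gene_id:
        raise ValueError(f"gene mismatch: occurrence {occ.gene_id!r} vs UTR {utr.gene_id!r}")
    if occ.seq_end > utr.seq_length:
        raise ValueError(
            f"{occ.gene_id}: site end {occ.seq_end} exceeds UTR length {utr.seq_length}"
        )
    if utr.strand == "+":
        start = utr.g_start + occ.seq_start - 1
        end = utr.g_start + occ.seq_end - 1
    else:
        start = utr.g_end - occ.seq_end + 1
        end = utr.g_end - occ.seq_start + 1
    return MappedMotif(
        gene_id=occ.gene_id, motif_id=occ.motif_id,
        chrom=utr.chrom, start=start, end=end,
    )


def map_to_sequence(start: int, end: int, utr: Utr3Interval) -> tuple[int, int]:
    """Inverse of :func:`map_to_genome`: genomic interval -> oriented sequence coords."""
    if not (utr.g_start <= start <= end <= utr.g_end):
        raise ValueError("genomic interval not contained in the UTR")
    if utr.strand == "+":
        return start - utr.g_start + 1, end - utr.g_start + 1
    return utr.g_end - end + 1, utr.g_end - start + 1


def project_occurrences(
    occurrences: Iterable[MotifOccurrence],
    utrs: Mapping[str, Utr3Interval],
) -> list[MappedMotif]:
    """Project a batch of occurrences; occurrences for genes without a UTR
    record are skipped with a warning."""
    mapped: list[MappedMotif] = []
    for occ in occurrences:
        utr = utrs.get(occ.gene_id)
        if utr is None:
            log.warning("no UTR interval for gene %s; occurrence skipped", occ.gene_id)
            continue
        mapped.append(map_to_genome(occ, utr))
    return mapped


# ---------------------------------------------------------------------------
# Containment


def variants_in_motifs(
    variants: Sequence[AnnotatedVariant],
    motif_intervals: Sequence[MappedMotif],
) -> list[MotifHit]:
    """Report every (variant, occurrence) pair where the variant's full
    interval lies inside the motif's genomic interval.

    Matching is chromosome-scoped; when the variant carries gene labels and
    the interval a gene id, the gene must also match, so coincident
    coordinates on different genes do not pair.  Uses a per-chromosome
    interval tree; results are sorted for stable output.
    """
    trees: dict[str, IntervalTree] = {}
    for m in motif_intervals:
        # half-open tree coords: [start, end+1) covers the inclusive interval
        trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end + 1, m)

    hits: list[MotifHit] = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(v.start, v.end + 1):
            m: MappedMotif = iv.data
            if not (m.start <= v.start and v.end <= m.end):
                continue
            if v.genes and m.gene_id and m.gene_id not in v.genes:
                continue
            hits.append(
                MotifHit(
                    variant=v, gene_id=m.gene_id, motif_id=m.motif_id,
                    chrom=m.chrom, motif_start=m.start, motif_end=m.end,
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.variant.start, h.motif_start, h.motif_id))
    return hits


# ---------------------------------------------------------------------------
# UTR interval table I/O

UTR_HEADER = ["gene", "chrom", "start", "end", "strand"]


def read_utr_table(path: Union[str, Path], bed: bool = False) -> dict[str, Utr3Interval]:
    """Read a UTR interval table (TSV with header gene, chrom, start, end, strand).

    By default coordinates are taken as 1-based inclusive; with ``bed=True``
    they are interpreted as 0-based half-open BED coordinates and converted
    (start+1, end unchanged).
    """
    out: dict[str, Utr3Interval] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return out
        missing = set(UTR_HEADER) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"UTR table missing columns {sorted(missing)}")
        for row in reader:
            start, end = int(row["start"]), int(row["end"])
            if bed:
                start += 1
            gene = row["gene"].strip()
            out[gene] = Utr3Interval(
                gene_id=gene,
                chrom=normalize_chrom(row["chrom"]),
                g_start=start,
                g_end=end,
                strand=row["strand"].strip(),
            )
    return out


def write_utr_table(utrs: Iterable[Utr3Interval], path: Union[str, Path]) -> None:
    """Write UTR intervals as the 1-based inclusive TSV read_utr_table expects."""
    with open(path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(UTR_HEADER)
        for u in utrs:
            w.writerow([u.gene_id, u.chrom, u.g_start, u.g_end, u.strand])


HITS_HEADER = [
    "trait", "gene", "chrom", "position", "ref", "alt",
    "motif_id", "motif_start", "motif_end", "offset",
]


def write_hits_tsv(hits: Sequence[MotifHit], dest: Union[str, Path]) -> None:
    """Write motif hits in the shape of the published per-trait hit tables."""
    with open(dest, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HITS_HEADER)
        for h in hits:
            v = h.variant
            w.writerow(
                [
                    v.trait_id, h.gene_id, h.chrom, v.start, v.ref_allele,
                    v.alt_allele, h.motif_id, h.motif_start, h.motif_end,
                    h.offset_in_motif,
                ]
            )
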