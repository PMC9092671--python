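"""Readers and normalizers for ANNOVAR-style annotation tables and gene lists.

ANNOVAR's ``variant_function`` output assigns each variant a region category
(exonic, intronic, UTR3, ...) and a gene field that may carry several comma-
or semicolon-separated symbols, each optionally suffixed with a distance
annotation like ``(dist=532)``.  Trait files exported from different sources
vary in delimiter, header presence and chromosome naming, so parsing is
driven by a configurable column map and everything is normalized on ingest:
coordinates are 1-based inclusive, ``chr`` prefixes are stripped, and region
categories are folded onto a fixed 13-token vocabulary.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence, TextIO, Union

log = logging.getLogger(__name__)

#: The canonical region-category vocabulary, in its conventional order.
REGION_CATEGORIES: tuple[str, ...] = (
    "intergenic",
    "intronic",
    "ncRNA_intronic",
    "UTR3",
    "exonic",
    "downstream",
    "upstream",
    "ncRNA_exonic",
    "UTR5",
    "upstream;downstream",
    "splicing",
    "ncRNA_splicing",
    "UTR5;UTR3",
)

#: Placeholder ANNOVAR writes when a variant has no associated gene.
GENE_NULL = "NONE"

_CANON = {tok.lower(): tok for tok in REGION_CATEGORIES}
# dialect spellings seen in exported tables ("3'UTR" with straight or curly quote)
_ALIASES = {
    "3'utr": "UTR3",
    "3’utr": "UTR3",
    "5'utr": "UTR5",
    "5’utr": "UTR5",
    "utr_3": "UTR3",
    "utr_5": "UTR5",
}

_DIST_RE = re.compile(r"\(dist=[^)]*\)")


def normalize_category(token: str) -> str | None:
    """Fold a raw category token onto the canonical vocabulary.

    Matching is case-insensitive and tolerant of the ``3'UTR``/``5'UTR``
    spellings; compound tokens (``upstream;downstream``) are normalized
    part-wise.  Returns ``None`` for tokens outside the vocabulary.
    Idempotent: canonical tokens map to themselves.
    """
    tok = token.strip()
    if not tok:
        return None
    low = tok.lower()
    if low in _CANON:
        return _CANON[low]
    if low in _ALIASES:
        return _ALIASES[low]
    if ";" in tok:
        parts = [normalize_category(p) for p in tok.split(";")]
        if all(p is not None for p in parts):
            joined = ";".join(p for p in parts if p is not None)
            return _CANON.get(joined.lower())
    return None


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``CHR`` prefix so ``chr6`` and ``6`` compare equal."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def parse_gene_field(raw: str) -> frozenset[str]:
    """Split an ANNOVAR gene field into a set of symbols.

    Splits on commas and semicolons, strips ``(dist=...)`` suffixes and
    whitespace; the ``NONE`` placeholder (or a blank field) yields the empty
    set.
    """
    raw = raw.strip()
    if not raw or raw == GENE_NULL:
        return frozenset()
    cleaned = _DIST_RE.sub("", raw)
    symbols = {s.strip() for s in re.split(r"[,;]", cleaned)}
    return frozenset(s for s in symbols if s and s != GENE_NULL)


class VariantKey(NamedTuple):
    """Trait-independent variant identity.

    ``full`` mode keys on (chrom, start, end, ref, alt); ``positional`` mode
    sets both alleles to ``None`` and keys on the locus alone.
    """

    chrom: str
    start: int
    end: int
    ref: str | None
    alt: str | None

    @property
    def mode(self) -> str:
        return "positional" if self.ref is None and self.alt is None else "full"


@dataclass(frozen=True)
class AnnotatedVariant:
    """One ANNOVAR-annotated variant record.

    Coordinates are 1-based inclusive (ANNOVAR convention); ``ref_allele`` /
    ``alt_allele`` use ``-`` for insertions/deletions as ANNOVAR does.
    ``genes`` is the parsed gene set; ``raw_gene_field`` preserves the
    original string.
    """

    trait_id: str
    chrom: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    category: str
    genes: frozenset[str] = frozenset()
    raw_gene_field: str = GENE_NULL

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"start ({self.start}) > end ({self.end}) for variant on {self.chrom}"
            )


def variant_key(v: AnnotatedVariant, mode: str = "full") -> VariantKey:
    """Build the cross-trait identity key for a variant."""
    if mode == "full":
        return VariantKey(v.chrom, v.start, v.end, v.ref_allele, v.alt_allele)
    if mode == "positional":
        return VariantKey(v.chrom, v.start, v.end, None, None)
    raise ValueError(f"unknown identity mode: {mode!r}")


@dataclass(frozen=True)
class RowError:
    """A malformed data row, kept for reporting rather than silently dropped."""

    line_no: int
    message: str
    raw: str = ""


@dataclass(frozen=True)
class ColumnMap:
    """Where to find each field in an annotation table.

    Each attribute is either a 0-based column index or a header name.  The
    default is ANNOVAR's ``variant_function`` layout: category, gene, chrom,
    start, end, ref, alt in the first seven columns, no header.
    """

    category: Union[int, str] = 0
    gene: Union[int, str] = 1
    chrom: Union[int, str] = 2
    start: Union[int, str] = 3
    end: Union[int, str] = 4
    ref: Union[int, str] = 5
    alt: Union[int, str] = 6

    def fields(self) -> dict[str, Union[int, str]]:
        return {
            "category": self.category,
            "gene": self.gene,
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "ref": self.ref,
            "alt": self.alt,
        }

    @property
    def uses_names(self) -> bool:
        return any(isinstance(v, str) for v in self.fields().values())


#: Column map matching :func:`write_variants_tsv` output, so normalized
#: tables round-trip through the parser.
NORMALIZED_COLUMNS = ColumnMap(
    category="category",
    gene="genes",
    chrom="chrom",
    start="start",
    end="end",
    ref="ref",
    alt="alt",
)


@dataclass
class ParseResult:
    """Outcome of parsing one annotation table.

    ``variants`` holds the accepted records, ``unclassified`` counts rows
    rejected for an unknown category token, and ``errors`` collects rows with
    malformed coordinates.  ``n_rows`` always equals the number of data rows
    in the file.
    """

    variants: list[AnnotatedVariant] = field(default_factory=list)
    unclassified: int = 0
    errors: list[RowError] = field(default_factory=list)
    trait_id: str = ""

    @property
    def n_rows(self) -> int:
        return len(self.variants) + self.unclassified + len(self.errors)


def _sniff_delimiter(first_line: str, dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    if dialect == "auto":
        return "\t" if "\t" in first_line else ","
    raise ValueError(f"unknown dialect: {dialect!r}")


def parse_annovar_table(
    path: Union[str, Path],
    trait_id: str | None = None,
    dialect: str = "auto",
    column_map: ColumnMap | None = None,
    has_header: Union[bool, str] = "auto",
) -> ParseResult:
    """Parse an ANNOVAR-style annotation table into normalized records.

    Parameters
    ----------
    path:
        The table file (TSV or CSV; ``dialect='auto'`` sniffs the first line).
    trait_id:
        Label stamped on every record; defaults to the file stem.
    column_map:
        Field locations; defaults to the ANNOVAR ``variant_function`` layout.
    has_header:
        ``True``/``False``, or ``'auto'``: a header is assumed whenever the
        column map uses names, otherwise detected by a non-numeric start
        field in the first row.

    Rows with an unknown category are counted under ``unclassified`` with a
    logged warning; rows with malformed coordinates become :class:`RowError`
    entries.  An empty file yields an empty result, not an error.
    """
    path = Path(path)
    if trait_id is None:
        trait_id = path.name.split(".")[0]
    cmap = column_map or ColumnMap()

    text = path.read_text()
    result = ParseResult(trait_id=trait_id)
    lines = text.splitlines()
    if not lines or all(not ln.strip() for ln in lines):
        return result

    first_data = next(ln for ln in lines if ln.strip())
    delim = _sniff_delimiter(first_data, dialect)
    rows = list(csv.reader(lines, delimiter=delim))
    rows = [r for r in rows if any(f.strip() for f in r)]

    header: list[str] | None = None
    if has_header == "auto":
        if cmap.uses_names:
            header_needed = True
        else:
            start_idx = cmap.start
            assert isinstance(start_idx, int)
            probe = rows[0][start_idx] if start_idx < len(rows[0]) else ""
            header_needed = not probe.strip().lstrip("-").isdigit()
        use_header = header_needed
    else:
        use_header = bool(has_header)
    if use_header:
        header = [h.strip() for h in rows[0]]
        rows = rows[1:]

    def resolve(spec: Union[int, str]) -> int:
        if isinstance(spec, int):
            return spec
        if header is None:
            raise ValueError(f"column {spec!r} named but file has no header")
        try:
            return header.index(spec)
        except ValueError:
            raise ValueError(f"column {spec!r} not found in header {header}") from None

    idx = {name: resolve(spec) for name, spec in cmap.fields().items()}
    width_needed = max(idx.values()) + 1

    for line_no, row in enumerate(rows, start=2 if use_header else 1):
        raw_line = delim.join(row)
        if len(row) < width_needed:
            result.errors.append(
                RowError(line_no, f"expected >= {width_needed} columns, got {len(row)}", raw_line)
            )
            continue
        raw_cat = row[idx["category"]]
        raw_gene = row[idx["gene"]].strip() or GENE_NULL
        try:
            start = int(row[idx["start"]].strip().replace(",", ""))
            end = int(row[idx["end"]].strip().replace(",", ""))
        except ValueError:
            result.errors.append(RowError(line_no, "non-numeric coordinates", raw_line))
            continue
        if start > end:
            result.errors.append(RowError(line_no, f"start {start} > end {end}", raw_line))
            continue
        category = normalize_category(raw_cat)
        if category is None:
            log.warning("%s line %d: unknown category %r", path.name, line_no, raw_cat)
            result.unclassified += 1
            continue
        ref = row[idx["ref"]].strip() or "-"
        alt = row[idx["alt"]].strip() or "-"
        result.variants.append(
            AnnotatedVariant(
                trait_id=trait_id,
                chrom=normalize_chrom(row[idx["chrom"]]),
                start=start,
                end=end,
                ref_allele=ref,
                alt_allele=alt,
                category=category,
                genes=parse_gene_field(raw_gene),
                raw_gene_field=raw_gene,
            )
        )
    return result


def read_gene_list(path: Union[str, Path]) -> set[str]:
    """Read a plain gene list (one symbol per line) into a set.

    Lines are whitespace-trimmed and case-preserved; blanks are skipped;
    duplicates collapse.
    """
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym:
            out.add(sym)
    return out


NORMALIZED_HEADER = ["trait", "chrom", "start", "end", "ref", "alt", "category", "genes"]


def write_variants_tsv(
    variants: Iterable[AnnotatedVariant], dest: Union[str, Path, TextIO]
) -> None:
    """Write records as a normalized TSV with a fixed column order.

    Genes are semicolon-joined in sorted order; the output parses back with
    :data:`NORMALIZED_COLUMNS`.
    """

    def emit(handle: TextIO) -> None:
        w = csv.writer(handle, delimiter="\t", lineterminator="\n")
        w.writerow(NORMALIZED_HEADER)
        for v in variants:
            w.writerow(
                [
                    v.trait_id,
                    v.chrom,
                    v.start,
                    v.end,
                    v.ref_allele,
                    v.alt_allele,
                    v.category,
                    ";".join(sorted(v.genes)) if v.genes else GENE_NULL,
                ]
            )

    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            emit(fh)
    else:
        emit(dest)
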