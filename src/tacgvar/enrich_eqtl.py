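"""eQTL eGene filtering, trait-gene overlap, and gene-set enrichment arithmetic.

The eQTL side consumes GTEx-style significant variant-gene pair tables and
retains, per tissue, the distinct genes whose best association passes a
Storey q-value cutoff and whose variant is common enough in the cohort:
strictly q < q_max and MAF > maf_min (both read literally as strict
inequalities).  The surviving genes are the tissue's eGenes; overlapping a
trait's miRNA-target genes with eGene sets yields the gene-by-tissue
presence matrix used to call trait-relevant tissues.

The enrichment side is deliberately plain arithmetic over caller-supplied
GMT annotations: for a study set of n genes with k annotated to a term, and
K of N background genes annotated,

    fold_enrichment = (k/n) / (K/N)
    p_hypergeom     = P(X >= k),  X ~ Hypergeom(N, K, n)
    p_ease          = P(X >= k-1)  (the EASE score: one success removed,
                                    a deliberately conservative variant)

with Benjamini-Hochberg adjustment across terms.  No term database or
web-service correction method is bundled.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(gene_id: str) -> str:
    """Drop a trailing Ensembl version suffix (``ENSG...X.12`` -> ``ENSG...X``)."""
    return _VERSION_RE.sub("", gene_id.strip())


@dataclass(frozen=True)
class EqtlRecord:
    """One significant variant-gene association in one tissue."""

    gene_id: str
    variant_id: str
    tissue: str
    qvalue: float
    maf: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"qvalue {self.qvalue} outside [0, 1]")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf {self.maf} outside (0, 0.5]")


@dataclass
class EGeneSet:
    """Distinct genes with at least one surviving eQTL in one tissue."""

    tissue: str
    genes: set[str]


def read_eqtl_table(
    path: Union[str, Path],
    gene_col: str = "gene_id",
    variant_col: str = "variant_id",
    tissue_col: str = "tissue",
    q_col: str = "qval",
    maf_col: str = "maf",
) -> list[EqtlRecord]:
    """Read a GTEx-style pair table (TSV) into records.

    Column names are configurable because exports differ; a missing column
    raises ``KeyError`` naming it.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (gene_col, variant_col, tissue_col, q_col, maf_col):
        if col not in df.columns:
            raise KeyError(f"eQTL table missing required column {col!r}")
    return [
        EqtlRecord(
            gene_id=str(r[gene_col]),
            variant_id=str(r[variant_col]),
            tissue=str(r[tissue_col]),
            qvalue=float(r[q_col]),
            maf=float(r[maf_col]),
        )
        for r in df.to_dict("records")
    ]


def filter_eqtl(
    records: Iterable[EqtlRecord], q_max: float = 0.05, maf_min: float = 0.05
) -> dict[str, EGeneSet]:
    """Per-tissue eGene sets under strict thresholds q < q_max, MAF > maf_min.

    Ensembl version suffixes are stripped before deduplication, so two
    records for the same gene at different annotation versions collapse.
    """
    out: dict[str, EGeneSet] = {}
    for rec in records:
        if rec.tissue not in out:
            out[rec.tissue] = EGeneSet(tissue=rec.tissue, genes=set())
        if rec.qvalue < q_max and rec.maf > maf_min:
            out[rec.tissue].genes.add(strip_version(rec.gene_id))
    return out


@dataclass
class OverlapResult:
    """Gene-by-tissue presence matrix plus per-tissue overlap counts."""

    presence: pd.DataFrame  # bool, index=study genes, columns=tissues
    counts: dict[str, int]
    unmapped: set[str]

    def to_yes_no_frame(self) -> pd.DataFrame:
        return self.presence.replace({True: "yes", False: "no"})


def egene_overlap(
    study_genes: set[str],
    egenes: Sequence[EGeneSet],
    id_map: Mapping[str, str] | None = None,
) -> OverlapResult:
    """Cross a study gene set with per-tissue eGene sets.

    ``id_map`` translates study identifiers (typically symbols) into the
    eGene identifier space (typically versionless Ensembl ids).  Study genes
    without a mapping are reported in ``unmapped`` and scored "no"
    everywhere, never silently dropped.
    """
    tissues = [e.tissue for e in egenes]
    unmapped: set[str] = set()
    rows: dict[str, list[bool]] = {}
    for gene in sorted(study_genes):
        if id_map is not None:
            target = id_map.get(gene)
            if target is None:
                unmapped.add(gene)
                rows[gene] = [False] * len(tissues)
                continue
        else:
            target = gene
        target = strip_version(target)
        rows[gene] = [target in e.genes for e in egenes]
    if unmapped:
        log.warning("%d study genes had no identifier mapping: %s",
                    len(unmapped), sorted(unmapped))
    presence = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    presence = presence.sort_index()
    counts = {t: int(presence[t].sum()) for t in tissues}
    return OverlapResult(presence=presence, counts=counts, unmapped=unmapped)


# ---------------------------------------------------------------------------
# Enrichment arithmetic


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # study genes annotated to the term
    n: int  # study size
    K: int  # background genes annotated to the term
    N: int  # background size
    fold_enrichment: float
    p_hypergeom: float
    p_ease: float
    p_adjusted: float | None = None


def read_gmt(path: Union[str, Path]) -> dict[str, set[str]]:
    """Read a GMT file (term, description, genes...) into term -> gene set."""
    terms: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line has fewer than 3 fields: {line[:80]!r}")
        terms[parts[0]] = {g.strip() for g in parts[2:] if g.strip()}
    return terms


def _upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); 1.0 when k <= 0."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    study_genes: set[str],
    term_annotations: Mapping[str, set[str]],
    background: set[str],
    method: str = "hypergeom",
) -> list[EnrichmentResult]:
    """Term-level fold enrichment and tail probabilities, BH-adjusted.

    The study set must lie inside the background; term gene sets are trimmed
    to the background (with a warning) so K never exceeds N.  ``method``
    selects which tail probability feeds the BH adjustment (``hypergeom`` or
    ``ease``); both raw values are always reported.  Terms with an empty
    trimmed annotation are dropped.  Results are sorted by the selected
    p-value, ascending.
    """
    if not background:
        raise ValueError("empty background")
    if method not in ("hypergeom", "ease"):
        raise ValueError(f"method must be 'hypergeom' or 'ease', got {method!r}")
    stray = study_genes - background
    if stray:
        raise ValueError(
            f"{len(stray)} study genes outside the background, e.g. {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(study_genes)
    results: list[EnrichmentResult] = []
    for term, genes in term_annotations.items():
        outside = genes - background
        if outside:
            log.warning("term %s: %d annotated genes outside background trimmed",
                        term, len(outside))
        trimmed = genes & background
        K = len(trimmed)
        if K == 0:
            continue
        k = len(study_genes & trimmed)
        fold = (k / n) / (K / N) if n else 0.0
        results.append(
            EnrichmentResult(
                term_id=term, k=k, n=n, K=K, N=N,
                fold_enrichment=fold,
                p_hypergeom=_upper_tail(k, N, K, n),
                p_ease=_upper_tail(k - 1, N, K, n),
            )
        )
    if results:
        raw = [r.p_hypergeom if method == "hypergeom" else r.p_ease for r in results]
        adjusted = multipletests(raw, method="fdr_bh")[1]
        for r, adj in zip(results, adjusted):
            r.p_adjusted = float(adj)
        results.sort(key=lambda r: (
            r.p_hypergeom if method == "hypergeom" else r.p_ease, r.term_id))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term_id, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "fold_enrichment": r.fold_enrichment,
                "p_hypergeom": r.p_hypergeom, "p_ease": r.p_ease,
                "p_adjusted": r.p_adjusted,
            }
            for r in results
        ]
    )
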