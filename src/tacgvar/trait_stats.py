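"""Per-trait region-category tallies and the 3'UTR prevalence statistic.

For each trait file the pipeline counts variants in every region category
and summarizes how strongly the trait's miRNA-target genes are hit by 3'UTR
variants.  Prevalence normalizes the 3'UTR signal by gene-set size:

    prevalence_pct = 100 * numerator / n_unique_genes

where the numerator is either the number of 3'UTR variant records
(``numerator_mode='variants'``, the default) or the number of distinct genes
carrying at least one 3'UTR variant (``'genes'``).  In variants mode the
statistic can legitimately exceed 100% when genes harbor several 3'UTR
variants each.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .io_annovar import (
    AnnotatedVariant,
    ColumnMap,
    ParseResult,
    REGION_CATEGORIES,
    parse_annovar_table,
)

log = logging.getLogger(__name__)

NUMERATOR_MODES = ("variants", "genes")


@dataclass
class CategoryCounts:
    """Variant tallies over the 13-token region vocabulary.

    ``counts`` is zero-filled for absent categories; ``unclassified`` counts
    rows whose token fell outside the vocabulary at parse time.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {tok: 0 for tok in REGION_CATEGORIES}
    )
    unclassified: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unclassified


@dataclass
class TraitSummary:
    """One trait's category tallies, gene counts and 3'UTR prevalence."""

    trait_id: str
    n_records: int
    category_counts: CategoryCounts
    n_unique_genes: int
    n_utr3_variants: int
    n_utr3_genes: int
    prevalence_pct: float
    numerator_mode: str = "variants"


def count_categories(
    variants: Sequence[AnnotatedVariant], unclassified: int = 0
) -> CategoryCounts:
    """Tally records over the full 13-token vocabulary, zero-filled."""
    cc = CategoryCounts(unclassified=unclassified)
    for v in variants:
        cc.counts[v.category] += 1
    return cc


def unique_genes(variants: Iterable[AnnotatedVariant]) -> set[str]:
    """Union of gene symbols across all records."""
    out: set[str] = set()
    for v in variants:
        out |= v.genes
    return out


def utr3_prevalence(
    variants: Sequence[AnnotatedVariant],
    numerator_mode: str = "variants",
    trait_id: str | None = None,
    unclassified: int = 0,
) -> TraitSummary:
    """Summarize one trait and compute its 3'UTR prevalence.

    Raises ``ValueError`` when the trait has no genes at all (the statistic
    is undefined, never silently zero) or for an unknown numerator mode.
    """
    if numerator_mode not in NUMERATOR_MODES:
        raise ValueError(f"numerator_mode must be one of {NUMERATOR_MODES}")
    if trait_id is None:
        trait_id = variants[0].trait_id if variants else ""
    all_genes = unique_genes(variants)
    if not all_genes:
        raise ValueError(
            f"trait {trait_id!r}: no gene symbols in input; prevalence is undefined"
        )
    utr3 = [v for v in variants if v.category == "UTR3"]
    n_utr3_genes = len(unique_genes(utr3))
    numerator = len(utr3) if numerator_mode == "variants" else n_utr3_genes
    return TraitSummary(
        trait_id=trait_id,
        n_records=len(variants) + unclassified,
        category_counts=count_categories(variants, unclassified=unclassified),
        n_unique_genes=len(all_genes),
        n_utr3_variants=len(utr3),
        n_utr3_genes=n_utr3_genes,
        prevalence_pct=100.0 * numerator / len(all_genes),
        numerator_mode=numerator_mode,
    )


def summarize_parse(result: ParseResult, numerator_mode: str = "variants") -> TraitSummary:
    """Summarize a :class:`ParseResult`, carrying its unclassified tally."""
    return utr3_prevalence(
        result.variants,
        numerator_mode=numerator_mode,
        trait_id=result.trait_id,
        unclassified=result.unclassified,
    )


def summarize_all(
    trait_files: Sequence[Union[str, Path]],
    numerator_mode: str = "variants",
    dialect: str = "auto",
    column_map: ColumnMap | None = None,
) -> list[TraitSummary]:
    """Summarize a batch of trait files, one row per trait.

    Individual file failures are logged and skipped; the run fails only if
    every file fails.  Output is ordered by trait_id.
    """
    if not trait_files:
        raise ValueError("no trait files supplied")
    summaries: list[TraitSummary] = []
    failures: list[str] = []
    for path in trait_files:
        try:
            res = parse_annovar_table(path, dialect=dialect, column_map=column_map)
            summaries.append(summarize_parse(res, numerator_mode=numerator_mode))
        except Exception as exc:  # noqa: BLE001 - per-file isolation is the contract
            log.warning("skipping %s: %s", path, exc)
            failures.append(str(path))
    if not summaries:
        raise RuntimeError(f"all {len(failures)} trait files failed to summarize")
    summaries.sort(key=lambda s: s.trait_id)
    return summaries


def summaries_to_frame(summaries: Sequence[TraitSummary]) -> pd.DataFrame:
    """Tabulate summaries: trait, record count, the 13 category columns,
    unclassified, gene counts, prevalence (rounded half-even to 1 decimal)
    and a rank column by prevalence descending."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"trait": s.trait_id, "n_records": s.n_records}
        row.update(s.category_counts.counts)
        row["unclassified"] = s.category_counts.unclassified
        row["n_unique_genes"] = s.n_unique_genes
        row["n_utr3_variants"] = s.n_utr3_variants
        row["n_utr3_genes"] = s.n_utr3_genes
        row["prevalence_pct"] = round(s.prevalence_pct, 1)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["prevalence_rank"] = (
        df["prevalence_pct"].rank(ascending=False, method="min").astype(int)
    )
    return df.sort_values("trait").reset_index(drop=True)


def summaries_to_json(summaries: Sequence[TraitSummary]) -> str:
    """JSON mirror of the summary table; prevalence kept at full precision."""
    payload = [
        {
            "trait": s.trait_id,
            "n_records": s.n_records,
            "category_counts": s.category_counts.counts,
            "unclassified": s.category_counts.unclassified,
            "n_unique_genes": s.n_unique_genes,
            "n_utr3_variants": s.n_utr3_variants,
            "n_utr3_genes": s.n_utr3_genes,
            "prevalence_pct": s.prevalence_pct,
            "numerator_mode": s.numerator_mode,
        }
        for s in summaries
    ]
    return json.dumps(payload, indent=2, sort_keys=True)
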