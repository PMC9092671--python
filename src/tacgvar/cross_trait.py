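"""Shared variants and shared genes between traits; all-pairs overlap matrices.

Variants that reach genome-wide significance for several traits point at
pleiotropic loci; here overlap is a pure set notion.  Each trait's variants
are deduplicated (by the configured identity mode) before counting, so a
variant repeated inside one file cannot inflate a pairwise count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .io_annovar import (
    ColumnMap,
    VariantKey,
    parse_annovar_table,
    read_gene_list,
    variant_key,
)

log = logging.getLogger(__name__)

OVERLAP_KINDS = ("variants", "genes")


def _check_modes(keys: set[VariantKey], label: str) -> str | None:
    modes = {k.mode for k in keys}
    if len(modes) > 1:
        raise ValueError(f"{label}: mixed variant identity modes {sorted(modes)}")
    return next(iter(modes)) if modes else None


def common_variants(a: set[VariantKey], b: set[VariantKey]) -> set[VariantKey]:
    """Exact intersection of two variant-key sets.

    Both sets must have been built with the same identity mode (full
    allele-aware keys or positional keys); mixing is an error.
    """
    mode_a = _check_modes(a, "first set")
    mode_b = _check_modes(b, "second set")
    if mode_a is not None and mode_b is not None and mode_a != mode_b:
        raise ValueError(
            f"identity mode mismatch: {mode_a!r} vs {mode_b!r}"
        )
    return a & b


def common_genes(sets: Sequence[set[str]]) -> set[str]:
    """Intersection of gene-symbol sets across all supplied traits."""
    if len(sets) < 2:
        raise ValueError("need at least two gene sets to intersect")
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


@dataclass
class OverlapMatrix:
    """Symmetric trait-by-trait shared-item counts.

    The diagonal holds each trait's deduplicated set size; off-diagonal cells
    hold pairwise intersection sizes, so every cell is bounded by the smaller
    of the two diagonal entries on its row/column.
    """

    trait_ids: list[str]
    counts: np.ndarray  # square, int64
    kind: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.trait_ids, columns=self.trait_ids)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format (traitA, traitB, count) over unordered pairs, for plotting."""
        rows = []
        for i, a in enumerate(self.trait_ids):
            for j in range(i + 1, len(self.trait_ids)):
                rows.append({"traitA": a, "traitB": self.trait_ids[j],
                             "count": int(self.counts[i, j])})
        return pd.DataFrame(rows)

    def nonzero_partner_counts(self) -> dict[str, int]:
        """Per trait, how many *other* traits share at least one item with it."""
        out = {}
        n = len(self.trait_ids)
        for i, t in enumerate(self.trait_ids):
            out[t] = int(sum(1 for j in range(n) if j != i and self.counts[i, j] > 0))
        return out


def build_overlap_matrix(
    trait_sets: Mapping[str, set], kind: str = "variants"
) -> OverlapMatrix:
    """All-pairs intersection counts over pre-built per-trait sets."""
    if kind not in OVERLAP_KINDS:
        raise ValueError(f"kind must be one of {OVERLAP_KINDS}")
    ids = sorted(trait_sets)
    n = len(ids)
    counts = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(ids):
        counts[i, i] = len(trait_sets[a])
        for j in range(i + 1, n):
            c = len(trait_sets[a] & trait_sets[ids[j]])
            counts[i, j] = counts[j, i] = c
    return OverlapMatrix(trait_ids=ids, counts=counts, kind=kind)


def load_trait_sets(
    trait_files: Sequence[Union[str, Path]],
    kind: str = "variants",
    identity_mode: str = "full",
    dialect: str = "auto",
    column_map: ColumnMap | None = None,
) -> dict[str, set]:
    """Build per-trait deduplicated sets from files.

    ``.txt`` files are read as plain gene lists (kind='genes' only); other
    files are parsed as annotation tables, from which variant keys or gene
    unions are taken.  Unreadable files are skipped with a warning.
    """
    sets: dict[str, set] = {}
    for path in trait_files:
        path = Path(path)
        try:
            if path.suffix == ".txt":
                if kind != "genes":
                    raise ValueError("plain gene lists only support kind='genes'")
                sets[path.name.split(".")[0]] = read_gene_list(path)
                continue
            res = parse_annovar_table(path, dialect=dialect, column_map=column_map)
            if kind == "variants":
                sets[res.trait_id] = {
                    variant_key(v, mode=identity_mode) for v in res.variants
                }
            else:
                genes: set[str] = set()
                for v in res.variants:
                    genes |= v.genes
                sets[res.trait_id] = genes
        except Exception as exc:  # noqa: BLE001 - per-file isolation
            log.warning("skipping %s: %s", path, exc)
    return sets


def overlap_matrix(
    trait_files: Sequence[Union[str, Path]],
    kind: str = "variants",
    identity_mode: str = "full",
    dialect: str = "auto",
    column_map: ColumnMap | None = None,
) -> OverlapMatrix:
    """All-pairs overlap matrix straight from trait files."""
    sets = load_trait_sets(
        trait_files, kind=kind, identity_mode=identity_mode,
        dialect=dialect, column_map=column_map,
    )
    if len(sets) < 2:
        raise ValueError("need at least two readable trait inputs")
    return build_overlap_matrix(sets, kind=kind)
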