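"""eGene filtering, trait-gene/eGene overlap, and enrichment arithmetic."""

import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tacgvar import datasets
from tacgvar.enrich_eqtl import (
    EGeneSet,
    EqtlRecord,
    egene_overlap,
    enrich,
    filter_eqtl,
    read_eqtl_table,
    read_gmt,
    strip_version,
)
from tacgvar.fixtures import gen_eqtl_table


def rec(gene="ENSG1.2", q=0.01, maf=0.2, tissue="T1", variant="v1"):
    return EqtlRecord(gene_id=gene, variant_id=variant, tissue=tissue,
                      qvalue=q, maf=maf)


class TestFilterEqtl:
    def test_q_boundary_is_strict(self):
        sets = filter_eqtl([rec(gene="A.1", q=0.049), rec(gene="B.1", q=0.05)])
        assert sets["T1"].genes == {"A"}

    def test_maf_boundary_is_strict(self):
        sets = filter_eqtl([rec(gene="A.1", maf=0.051), rec(gene="B.1", maf=0.05)])
        assert sets["T1"].genes == {"A"}

    def test_version_suffixes_collapse(self):
        sets = filter_eqtl([rec(gene="ENSG7.1"), rec(gene="ENSG7.4", variant="v2")])
        assert sets["T1"].genes == {"ENSG7"}

    def test_planted_egenes_recovered(self):
        records = [rec(gene=f"G{i}.1", q=0.001, maf=0.3, variant=f"v{i}")
                   for i in range(7)]
        records += [rec(gene=f"G{i}.1", q=0.8, maf=0.3, variant=f"v{i}")
                    for i in range(7, 20)]
        sets = filter_eqtl(records)
        assert sets["T1"].genes == {f"G{i}" for i in range(7)}

    def test_monotone_in_both_thresholds(self):
        """Relaxing q_max or maf_min never shrinks an eGene set."""
        import numpy as np

        rng = np.random.default_rng(17)
        records = [
            rec(gene=f"G{i}.1", q=float(rng.uniform(0, 0.2)),
                maf=float(rng.uniform(0.001, 0.5)), variant=f"v{i}")
            for i in range(200)
        ]
        grid = [0.01, 0.03, 0.05, 0.1]
        for maf_min in (0.01, 0.05, 0.1):
            sizes = [len(filter_eqtl(records, q_max=q, maf_min=maf_min)["T1"].genes)
                     for q in grid]
            assert sizes == sorted(sizes)
        for q_max in grid:
            sizes = [len(filter_eqtl(records, q_max=q_max, maf_min=m)["T1"].genes)
                     for m in (0.1, 0.05, 0.01)]
            assert sizes == sorted(sizes)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "eqtl.tsv"
        p.write_text("gene_id\tvariant_id\ttissue\tqval\nA\tv\tT\t0.01\n")
        with pytest.raises(KeyError, match="maf"):
            read_eqtl_table(p)

    def test_generated_fixture_recovered(self, tmp_path):
        ledger = gen_eqtl_table(tmp_path / "e", n_genes=60, frac_egenes=0.25, seed=2)
        records = read_eqtl_table(tmp_path / "e" / "eqtl_pairs.tsv")
        sets = filter_eqtl(records)
        for tissue, planted in ledger.egenes.items():
            assert sorted(sets[tissue].genes) == planted

    def test_record_range_validation(self):
        with pytest.raises(ValueError):
            rec(q=1.5)
        with pytest.raises(ValueError):
            rec(maf=0.7)


class TestEgeneOverlap:
    def table2_sets(self):
        tissues = [datasets.ADIPOSE_SUBCUTANEOUS, datasets.ADIPOSE_VISCERAL_OMENTUM]
        return [
            EGeneSet(tissue=t, genes={g for g, row in
                                      datasets.CHILD_OBESITY_EGENE_TABLE.items()
                                      if row[t]})
            for t in tissues
        ]

    def test_published_adipose_counts(self):
        """Re-encoding the published gene-by-tissue table gives 10 target
        genes in subcutaneous and 9 in visceral-omentum adipose eGenes."""
        result = egene_overlap(set(datasets.CHILD_OBESITY_EGENE_TABLE),
                               self.table2_sets())
        assert result.counts[datasets.ADIPOSE_SUBCUTANEOUS] == 10
        assert result.counts[datasets.ADIPOSE_VISCERAL_OMENTUM] == 9

    def test_empty_study_set(self):
        result = egene_overlap(set(), self.table2_sets())
        assert all(c == 0 for c in result.counts.values())

    def test_study_inside_every_tissue(self):
        sets = [EGeneSet("T1", {"A", "B", "C"}), EGeneSet("T2", {"A", "B", "C", "D"})]
        result = egene_overlap({"A", "B"}, sets)
        assert result.counts == {"T1": 2, "T2": 2}

    def test_tissue_order_and_duplicates_invariant(self):
        sets = self.table2_sets()
        study = set(datasets.CHILD_OBESITY_EGENE_TABLE)
        fwd = egene_overlap(study, sets).counts
        rev = egene_overlap(study, sets[::-1]).counts
        assert fwd == rev

    def test_unmapped_genes_scored_no_not_dropped(self):
        id_map = {"FTO": "ENSG00000140718"}
        sets = [EGeneSet("T1", {"ENSG00000140718"})]
        result = egene_overlap({"FTO", "MYSTERY"}, sets, id_map=id_map)
        assert result.counts["T1"] == 1
        assert result.unmapped == {"MYSTERY"}
        assert result.presence.loc["MYSTERY", "T1"] == False  # noqa: E712

    def test_yes_no_frame_shape(self):
        result = egene_overlap(set(datasets.CHILD_OBESITY_EGENE_TABLE),
                               self.table2_sets())
        yn = result.to_yes_no_frame()
        assert yn.loc["CLVS1", datasets.ADIPOSE_VISCERAL_OMENTUM] == "no"
        assert yn.loc["CLVS1", datasets.ADIPOSE_SUBCUTANEOUS] == "yes"


def enumeration_tail(k, N, K, n):
    """Brute-force P(X >= k): enumerate every n-draw from N items of which K
    are successes."""
    if k <= 0:
        return 1.0
    items = list(range(N))
    hits = 0
    total = 0
    for draw in itertools.combinations(items, n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total if total else 1.0


class TestEnrichment:
    def test_tail_matches_exhaustive_enumeration_smallN(self):
        """Closed-form hypergeometric upper tail equals draw-by-draw
        enumeration for every (N, K, n, k) with N <= 12."""
        genes = [f"G{i}" for i in range(12)]
        for N in range(1, 13):
            background = set(genes[:N])
            for K in range(0, N + 1):
                term = {"term": set(genes[:K])}
                for n in range(1, N + 1):
                    study = set(genes[N - n: N])
                    results = enrich(study, term, background)
                    if K == 0:
                        assert results == []
                        continue
                    (r,) = results
                    k = len(study & term["term"])
                    expected = enumeration_tail(k, N, K, n)
                    assert math.isclose(r.p_hypergeom, expected, abs_tol=1e-12)

    def test_specific_enumeration_case(self):
        genes = [f"G{i}" for i in range(10)]
        background = set(genes)
        term = {"t": set(genes[:4])}
        study = set(genes[:3]) | {genes[8], genes[9]}  # k=3, n=5
        (r,) = enrich(study, term, background)
        assert r.k == 3 and r.n == 5 and r.K == 4 and r.N == 10
        assert math.isclose(r.p_hypergeom, enumeration_tail(3, 10, 4, 5), abs_tol=1e-12)

    def test_saturation_fold_is_one(self):
        genes = {f"G{i}" for i in range(8)}
        (r,) = enrich(genes, {"t": set(genes)}, set(genes))
        assert r.fold_enrichment == pytest.approx(1.0)
        assert r.k == r.n and r.K == r.N

    def test_published_fold_arithmetic(self):
        """5 of 16 study genes on a term at background frequency ~0.0934
        gives the published DNA-binding fold of about 3.3465."""
        background = {f"B{i:03d}" for i in range(846)}
        ordered = sorted(background)
        term = set(ordered[:79])
        study = set(ordered[:5]) | set(ordered[-11:])
        (r,) = enrich(study, {"DNA-binding": term}, background)
        assert r.k == 5 and r.n == 16 and r.K == 79 and r.N == 846
        assert r.fold_enrichment == pytest.approx(3.3465, abs=0.001)

    @given(st.integers(2, 40), st.integers(1, 20), st.integers(1, 20),
           st.integers(0, 20))
    def test_ease_at_least_hypergeom(self, N, K, n, seedk):
        K = min(K, N)
        n = min(n, N)
        genes = [f"G{i}" for i in range(N)]
        background = set(genes)
        study = set(genes[:n])
        term = set(genes[seedk % N:][:K])
        results = enrich(study, {"t": term}, background)
        if not results:
            return
        (r,) = results
        assert r.p_ease >= r.p_hypergeom - 1e-12
        assert 0 < r.p_ease <= 1 and 0 < r.p_hypergeom <= 1

    def test_study_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside the background"):
            enrich({"X"}, {"t": {"A"}}, {"A", "B"})

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="empty background"):
            enrich(set(), {"t": {"A"}}, set())

    def test_bh_adjustment_present_and_bounded(self):
        genes = [f"G{i}" for i in range(30)]
        background = set(genes)
        study = set(genes[:6])
        terms = {f"t{j}": set(genes[j: j + 8]) for j in range(5)}
        results = enrich(study, terms, background)
        for r in results:
            assert r.p_adjusted is not None
            assert r.p_adjusted >= r.p_hypergeom - 1e-12

    def test_read_gmt(self, tmp_path):
        p = tmp_path / "terms.gmt"
        p.write_text("t1\tdesc\tA\tB\tC\nt2\tdesc\tB\n")
        terms = read_gmt(p)
        assert terms == {"t1": {"A", "B", "C"}, "t2": {"B"}}

    def test_strip_version(self):
        assert strip_version("ENSG00000140718.20") == "ENSG00000140718"
        assert strip_version("FTO") == "FTO"
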