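"""Published reference values bundled for worked examples and checks.

These are small literature-reported inputs for the child-obesity and
blood-trait analyses the pipeline was designed around: the child-obesity
miRNA-target gene list, the gene-by-adipose-tissue eGene presence table,
and the two worked motif-hit examples (a PIM1 3'UTR variant inside a
hemoglobin-trait motif and a LUC7L3 variant inside a red-blood-cell-count
motif).  They are inputs to the pipeline, not outputs of it.
"""

from __future__ import annotations

from .io_annovar import AnnotatedVariant
from .motif_map import MappedMotif

#: miRNA-target genes reported for the child-obesity trait (16 unique symbols).
CHILD_OBESITY_TARGET_GENES: frozenset[str] = frozenset(
    {
        "ZNF566", "RC3H1", "KCTD15", "FTO", "ARSJ", "GMEB1", "CEP120",
        "PIGN", "ETV7", "ZBTB40", "NFIX", "WDR55", "C1orf173",
        "FAM114A1", "CD59", "CLVS1",
    }
)

ADIPOSE_SUBCUTANEOUS = "Adipose_Subcutaneous"
ADIPOSE_VISCERAL_OMENTUM = "Adipose_Visceral_Omentum"

#: Published gene-by-tissue eGene status for the child-obesity target genes
#: that are eGenes in at least one of the two adipose tissues.
CHILD_OBESITY_EGENE_TABLE: dict[str, dict[str, bool]] = {
    "ZNF566": {ADIPOSE_SUBCUTANEOUS: True, ADIPOSE_VISCERAL_OMENTUM: True},
    "KCTD15": {ADIPOSE_SUBCUTANEOUS: True, ADIPOSE_VISCERAL_OMENTUM: True},
    "FTO": {ADIPOSE_SUBCUTANEOUS: True, ADIPOSE_VISCERAL_OMENTUM: True},
    "CEP120": {ADIPOSE_SUBCUTANEOUS: True, ADIPOSE_VISCERAL_OMENTUM: True},
    "PIGN": {ADIPOSE_SUBCUTANEOUS: True, ADIPOSE_VISCERAL_OMENTUM: True},
    "ETV7": {ADIPOSE_SUBCUTANEOUS: True, ADIPOSE_VISCERAL_OMENTUM: True},
    "WDR55": {ADIPOSE_SUBCUTANEOUS: True, ADIPOSE_VISCERAL_OMENTUM: True},
    "FAM114A1": {ADIPOSE_SUBCUTANEOUS: True, ADIPOSE_VISCERAL_OMENTUM: True},
    "CD59": {ADIPOSE_SUBCUTANEOUS: True, ADIPOSE_VISCERAL_OMENTUM: True},
    "CLVS1": {ADIPOSE_SUBCUTANEOUS: True, ADIPOSE_VISCERAL_OMENTUM: False},
}

#: Genes shared by the red-blood-cell-count, hemoglobin and packed-cell-volume
#: traits in the published cross-trait overlap.
ERYTHROCYTE_TRAIT_COMMON_GENES: frozenset[str] = frozenset(
    {"TFPI", "HBS1L", "MED1", "PIK3R3"}
)

#: Worked example: PIM1 3'UTR variant (C>T, chr6:37,174,646) and the
#: hemoglobin-trait motif interval it falls inside.
PIM1_VARIANT = AnnotatedVariant(
    trait_id="HB", chrom="6", start=37174646, end=37174646,
    ref_allele="C", alt_allele="T", category="UTR3",
    genes=frozenset({"PIM1"}), raw_gene_field="PIM1",
)
HB_PIM1_MOTIF = MappedMotif(
    gene_id="PIM1", motif_id="HB_motif_1", chrom="6",
    start=37174641, end=37174660,
)

#: Worked example: LUC7L3 3'UTR variant (T>C, chr17:50,753,923) and the
#: red-blood-cell-count motif interval it falls inside.
LUC7L3_VARIANT = AnnotatedVariant(
    trait_id="RBC", chrom="17", start=50753923, end=50753923,
    ref_allele="T", alt_allele="C", category="UTR3",
    genes=frozenset({"LUC7L3"}), raw_gene_field="LUC7L3",
)
RBC_LUC7L3_MOTIF = MappedMotif(
    gene_id="LUC7L3", motif_id="RBC_motif_1", chrom="17",
    start=50753918, end=50753937,
)
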