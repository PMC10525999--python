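"""Published summary data for the *Tylosema esculentum* (marama bean)
organelle-genome population study.

These small tables are printed results from the published comparative
analysis of 84 marama individuals (reference mitogenome chromosomes
OK638188/OK638189, type 2 assembly OP795447-OP795450, plastome
KX792933.1).  They serve as inputs for desk-scale reanalysis — e.g. the
quartet-parsimony origin assignment of variants inside the shared 9,798 bp
chloroplast insertion — and as cross-checks for the pipeline's aggregation
arithmetic.
"""

from __future__ import annotations

import pandas as pd

from .cporigin import QuadPattern

# ---------------------------------------------------------------------------
# Chromosome base composition of the type 2 mitogenome assembly
# (molecule, A%, C%, G%, T%, GC%, length bp)

TYPE2_CHROMOSOME_COMPOSITION = pd.DataFrame(
    [
        ("M1", 27.90, 22.18, 22.22, 27.70, 44.40, 169_406),
        ("M2", 27.60, 21.63, 23.26, 27.52, 44.90, 56_355),
        ("M3", 27.46, 22.25, 22.73, 27.55, 45.00, 97_120),
        ("M4", 27.70, 22.58, 22.44, 27.29, 45.00, 113_687),
    ],
    columns=["molecule", "A", "C", "G", "T", "GC", "length"],
)


def length_weighted_gc(composition: pd.DataFrame = TYPE2_CHROMOSOME_COMPOSITION) -> float:
    """Genome-wide GC percentage as the length-weighted mean of the
    per-chromosome GC percentages."""
    w = composition["length"]
    return float((composition["GC"] * w).sum() / w.sum())


def total_genome_length(composition: pd.DataFrame = TYPE2_CHROMOSOME_COMPOSITION) -> int:
    return int(composition["length"].sum())


# ---------------------------------------------------------------------------
# Population variant counts per reference chromosome and variant class.
# `type2_vs_ref` / `type1_vs_ref` count loci where samples of that type
# differ from the reference; `*_exclusive` are the loci variant in samples
# of exactly one type.  A locus can be variant in both columns, so the
# per-class `total` counts distinct loci, not the column sum.

POPULATION_VARIANT_COUNTS = pd.DataFrame(
    [
        ("LS1", "DEL", 29, 29, 3, 3, 32),
        ("LS1", "INS", 34, 34, 0, 0, 34),
        ("LS1", "SNP", 79, 75, 13, 9, 88),
        ("LS2", "DEL", 25, 21, 7, 3, 27),
        ("LS2", "INS", 18, 17, 1, 0, 18),
        ("LS2", "SNP", 54, 54, 1, 1, 55),
    ],
    columns=[
        "chromosome",
        "variant_class",
        "type2_vs_ref",
        "type2_exclusive",
        "type1_vs_ref",
        "type1_exclusive",
        "total",
    ],
)

N_TYPE1_INDIVIDUALS = 45
N_TYPE2_INDIVIDUALS = 39

# ---------------------------------------------------------------------------
# Variants falling inside mitochondrial gene sequences
# (chromosome, 1-based position, variant class, gene, region)

GENE_SEQUENCE_VARIANTS = pd.DataFrame(
    [
        ("LS1", 54_113, "Indel", "nad7", "Intron"),
        ("LS2", 2_368, "SNP", "matR", "Exon"),
        ("LS2", 35_483, "Indel", "nad4", "Intron"),
        ("LS2", 37_645, "SNP", "nad4", "Intron"),
        ("LS2", 39_597, "Indel", "nad4", "Intron"),
        ("LS2", 40_927, "SNP", "nad4", "Intron"),
        ("LS2", 41_027, "Indel", "nad4", "Intron"),
        ("LS2", 56_879, "SNP", "rps3", "Intron"),
        ("LS2", 69_748, "SNP", "nad2", "Intron"),
        ("LS2", 71_388, "Indel", "nad2", "Intron"),
        ("LS2", 71_633, "Indel", "nad2", "Intron"),
    ],
    columns=["chromosome", "position", "variant_class", "gene", "region"],
)

# ---------------------------------------------------------------------------
# Published inter-type differential loci on the 9,798 bp chloroplast
# insertion shared by both organelle genomes.  States are relative to the
# type-1 chloroplast reference, in the order (type1-chloro, type1-mito,
# type2-chloro, type2-mito).  The published localization column records
# the lineage the original analysis attributed each mutation to.

_INSERTION_LOCI_ROWS = [
    # position, class, cT1, mT1, cT2, mT2, polymorphic, published localization
    (35_570, "SNP", "Ref", "Alt", "Ref", "Ref", False, "Mito"),
    (36_347, "DEL", "Ref", "Alt", "Ref", "Ref", False, "Mito"),
    (36_942, "SNP", "Ref", "Ref", "Alt", "Ref", False, "Chloro"),
    (37_257, "SNP", "Ref", "Alt", "Alt", "Alt", False, "Chloro"),
    (37_813, "SNP", "Alt", "Ref", "Ref", "Ref", True, "Chloro"),
    (38_753, "DEL", "Ref", "Ref", "Ref", "Alt", False, "Mito"),
    (38_975, "SNP", "Ref", "Ref", "Alt", "Ref", False, "Chloro"),
    (39_429, "SNP", "Ref", "Alt", "Ref", "Ref", False, "Mito"),
    (40_061, "SNP", "Ref", "Alt", "Ref", "Ref", False, "Mito"),
    (40_544, "SNP", "Ref", "Alt", "Ref", "Ref", False, "Mito"),
    (41_243, "SNP", "Ref", "Alt", "Alt", "Alt", False, "Chloro"),
    (41_716, "SNP", "Ref", "Ref", "Ref", "Alt", False, "Mito"),
    (41_718, "SNP", "Ref", "Ref", "Ref", "Alt", False, "Mito"),
    (42_587, "SNP", "Ref", "Ref", "Alt", "Ref", False, "Chloro"),
    (43_559, "SNP", "Ref", "Ref", "Ref", "Alt", False, "Mito"),
    (44_059, "INS", "Ref", "Alt", "Alt", "Alt", False, "Chloro"),
    (44_235, "DEL", "Ref", "Alt", "Ref", "Ref", False, "Mito"),
    (44_302, "SNP", "Ref", "Alt", "Ref", "Ref", False, "Mito"),
    (44_552, "SNP", "Ref", "Ref", "Ref", "Alt", False, "Mito"),
    (44_762, "DEL", "Ref", "Ref", "Ref", "Alt", False, "Mito"),
]


def insertion_quad_patterns() -> list[QuadPattern]:
    """The 20 inter-type differential loci of the shared chloroplast
    insertion, as quad patterns ready for origin assignment."""
    return [
        QuadPattern(
            locus=f"LS2:{pos}",
            chloro_t1=c1,
            mito_t1=m1,
            chloro_t2=c2,
            mito_t2=m2,
            variant_class=cls,
            polymorphic=poly,
        )
        for pos, cls, c1, m1, c2, m2, poly, _loc in _INSERTION_LOCI_ROWS
    ]


def insertion_published_localizations() -> list[str]:
    """Published per-locus localization (same row order as
    :func:`insertion_quad_patterns`)."""
    return [row[-1] for row in _INSERTION_LOCI_ROWS]


# ---------------------------------------------------------------------------
# Published primer pairs (all verified by gel in the original study)

# Across the ends of the 2,108 bp type-2-exclusive marker fragment
MARKER_PRIMERS = {
    "left": ("GAGACCGAGCGCAAGAACTA", "TCAGATGGCTAAACAGGCGG", 990),
    "right": ("CGCTCGTGACTCATTGAGGA", "TTGGTAAGCGGATGCTCTGG", 289),
}

# Across the ends of the 9,798 bp chloroplast insertion, in the
# mitogenome and the plastome respectively
INSERTION_PRIMERS = {
    "mito_left": ("ACGCAGAAAAGAGGCCGAA", "CCTTCGTTTAAGAGAATGTTTTTGG", 117),
    "mito_right": ("TCTTTGCTACAGCTGATAAAAATCG", "CCTATGTTCGTTTTCGCCCTG", 120),
    "chloro_left": ("CGTAGTCGGTCTGGCCC", "CCTTCGTTTAAGAGAATGTTTTTGG", 117),
    "chloro_right": ("TCTTTGCTACAGCTGATAAAAATCG", "GCTTTTAATAATATGGCCGTGATCT", 120),
}
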