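"""Heteroplasmy filters, variant calling, masking, typing, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopop import forge, variants
from mitopop.core import Molecule
from mitopop.io import PILEUP_COLUMNS, PileupTable
from mitopop.variants import (
    GermplasmAssignment,
    HetFilterParams,
    VariantMatrix,
    aggregate_counts,
    build_homology_mask,
    build_variant_matrix,
    call_heteroplasmy,
    call_variants,
    type_samples,
    variant_count_totals,
)


def _pileup(rows):
    return PileupTable(pd.DataFrame(rows, columns=PILEUP_COLUMNS))


# ---------------------------------------------------------------------------
# Heteroplasmy filters


def test_four_percent_minor_allele_recorded():
    # 96 major / 4 minor (2 fwd + 2 rev): recorded at frequency 0.04
    t = _pileup([("M1", 10, "A", 48, 48), ("M1", 10, "G", 2, 2)])
    recs = call_heteroplasmy(t)
    assert len(recs) == 1
    r = recs[0]
    assert (r.minor_allele, r.minor_freq) == ("G", pytest.approx(0.04))
    assert (r.major_allele, r.major_freq) == ("A", pytest.approx(0.96))
    assert (r.minor_fwd, r.minor_rev) == (2, 2)


def test_one_percent_minor_allele_below_threshold():
    t = _pileup([("M1", 10, "A", 50, 49), ("M1", 10, "G", 1, 0)])
    assert call_heteroplasmy(t) == []


def test_single_strand_minor_allele_rejected():
    # 10% frequency but all reads on the forward strand
    t = _pileup([("M1", 10, "A", 45, 45), ("M1", 10, "G", 10, 0)])
    assert call_heteroplasmy(t) == []
    params = HetFilterParams(require_both_strands=False)
    assert len(call_heteroplasmy(t, params)) == 1


def test_masked_locus_rejected():
    t = _pileup([("M1", 10, "A", 48, 47), ("M1", 10, "G", 3, 2)])
    params = HetFilterParams(mask={"M1": [(5, 20)]})
    assert call_heteroplasmy(t, params) == []
    params = HetFilterParams(mask={"M1": [(50, 60)]})
    assert len(call_heteroplasmy(t, params)) == 1


def _row_oracle(sub, params):
    """Independent per-locus filter, straight from the rules."""
    totals = {a: f + r for a, f, r in zip(sub["allele"], sub["fwd"], sub["rev"])}
    depth = sum(totals.values())
    if depth == 0:
        return []
    major = max(sorted(totals), key=lambda a: totals[a])
    recorded = []
    for _, row in sub.iterrows():
        a = row["allele"]
        if a == major:
            continue
        if totals[a] / depth < params.min_minor_freq:
            continue
        if params.require_both_strands and (row["fwd"] < 1 or row["rev"] < 1):
            continue
        recorded.append(a)
    return sorted(recorded)


count_rows = st.lists(
    st.tuples(
        st.integers(1, 3),  # position
        st.sampled_from(["A", "C", "G", "T", "+AT", "-G"]),
        st.integers(0, 60),
        st.integers(0, 60),
    ),
    min_size=1,
    max_size=12,
)


@settings(max_examples=200, derandomize=True)
@given(rows=count_rows, freq=st.sampled_from([0.02, 0.05, 0.1, 0.3]))
def test_caller_equals_row_oracle_on_random_tables(rows, freq):
    seen = set()
    table_rows = []
    for pos, allele, f, r in rows:
        if (pos, allele) in seen:
            continue
        seen.add((pos, allele))
        table_rows.append(("M1", pos, allele, f, r))
    t = _pileup(table_rows)
    params = HetFilterParams(min_minor_freq=freq)
    got = {}
    for rec in call_heteroplasmy(t, params):
        got.setdefault(rec.pos, []).append(rec.minor_allele)
    df = t.df
    for pos, sub in df.groupby("pos"):
        expected = _row_oracle(sub, params)
        assert sorted(got.get(pos, [])) == expected, pos


@settings(max_examples=100, derandomize=True)
@given(rows=count_rows)
def test_raising_threshold_never_adds_records(rows):
    seen, table_rows = set(), []
    for pos, allele, f, r in rows:
        if (pos, allele) not in seen:
            seen.add((pos, allele))
            table_rows.append(("M1", pos, allele, f, r))
    t = _pileup(table_rows)
    keys = None
    for freq in (0.02, 0.05, 0.1, 0.2, 0.4):
        recs = {(r.pos, r.minor_allele) for r in call_heteroplasmy(t, HetFilterParams(min_minor_freq=freq))}
        if keys is not None:
            assert recs <= keys
        keys = recs


def test_params_validated():
    with pytest.raises(ValueError):
        HetFilterParams(min_minor_freq=0.6)
    with pytest.raises(ValueError):
        HetFilterParams(min_minor_freq=0.0)


# ---------------------------------------------------------------------------
# Variant calling


REF = {"M1": "C" * 100, "M2": "G" * 100}


def test_majority_nonreference_allele_called_snp():
    t = _pileup([("M1", 10, "T", 50, 50)])
    result = call_variants(t, REF)
    assert len(result.calls) == 1
    c = result.calls[0]
    assert (c.ref_allele, c.alt_allele, c.variant_class) == ("C", "T", "SNP")


def test_majority_deletion_called():
    t = _pileup([("M1", 20, "-CCC", 30, 30), ("M1", 20, "C", 20, 20)])
    result = call_variants(t, REF)
    assert result.calls[0].variant_class == "DEL"
    assert result.calls[0].alt_allele == "-CCC"


def test_below_min_depth_is_nocall():
    t = _pileup([("M1", 30, "T", 3, 2)])
    result = call_variants(t, REF, min_depth=10)
    assert result.calls == [] and result.nocalls == [("M1", 30)]


def test_reference_match_is_not_a_call():
    t = _pileup([("M1", 40, "C", 30, 30)])
    result = call_variants(t, REF)
    assert result.calls == [] and result.nocalls == []


# ---------------------------------------------------------------------------
# Homology mask


def test_decoy_copy_masked_and_insertion_kept(small_truth):
    mito = list(small_truth.genomes["type1"])
    keep = {
        small_truth.cp_insert["mito_molecule"]: [
            small_truth.cp_insert["mito_interval"]
        ]
    }
    mask = build_homology_mask(
        mito,
        small_truth.plastomes["type1"],
        list(small_truth.decoys.values()),
        min_len=500,
        keep_intervals=keep,
    )
    (mol, (lo, hi)), = [
        (m, iv) for m, ivs in small_truth.mask_truth.items() for iv in ivs
    ]
    assert any(
        s <= lo + 100 and e >= hi - 100 for s, e in mask.get(mol, [])
    ), "decoy-homologous segment not masked"
    # the registered insertion interval is analysed, never masked
    ins_mol = small_truth.cp_insert["mito_molecule"]
    ins_lo, ins_hi = small_truth.cp_insert["mito_interval"]
    overlap_bp = sum(
        max(0, min(e, ins_hi) - max(s, ins_lo) + 1)
        for s, e in mask.get(ins_mol, [])
    )
    assert overlap_bp == 0


def test_no_targets_empty_mask(small_truth):
    mito = list(small_truth.genomes["type1"])
    assert build_homology_mask(mito, None, []) == {}


# ---------------------------------------------------------------------------
# Typing


def _typing_matrix():
    loci = [("M1", p, "SNP") for p in (10, 20, 30, 40)]
    refs = ["A", "A", "A", "A"]
    alts = ["G", "G", "G", "G"]
    cells = {
        "pure2": ["G", "G", "G", "G"],
        "pure1": ["A", "A", "A", "A"],
        "uncovered": [None, None, None, None],
    }
    return VariantMatrix(["pure1", "pure2", "uncovered"], loci, refs, alts, cells)


def test_type_assignment_by_majority_vote():
    m = _typing_matrix()
    alleles = [("A", "G")] * 4
    marker = {"pure1": 2.0, "pure2": 95.0, "uncovered": 0.0}
    med = {"pure1": 100.0, "pure2": 100.0, "uncovered": 100.0}
    result = {a.sample: a for a in type_samples(m, alleles, marker, med)}
    assert result["pure2"].assigned_type == "type2"
    assert result["pure2"].marker_present and not result["pure2"].discordant
    assert result["pure1"].assigned_type == "type1"
    assert not result["pure1"].marker_present
    assert result["uncovered"].assigned_type is None


def test_heteroplasmic_sample_votes_major_type_with_het_summary():
    m = _typing_matrix()
    alleles = [("A", "G")] * 4
    het = {"pure1": 0.04}
    result = {
        a.sample: a for a in type_samples(m, alleles, het_summary=het)
    }
    assert result["pure1"].assigned_type == "type1"
    assert result["pure1"].het_median_minor_freq == pytest.approx(0.04)


def test_marker_vote_discordance_reported_not_resolved():
    m = _typing_matrix()
    alleles = [("A", "G")] * 4
    marker = {"pure2": 1.0}  # marker absent though alleles say type 2
    med = {"pure2": 100.0}
    result = {a.sample: a for a in type_samples(m, alleles, marker, med)}
    assert result["pure2"].assigned_type == "type2"
    assert result["pure2"].discordant


# ---------------------------------------------------------------------------
# Aggregation


def test_forge_population_aggregation_matches_truth(small_truth):
    samples = list(small_truth.samples["sample"])
    reference = small_truth.reference_sequences()
    call_sets = {
        s: call_variants(forge.simulate_allele_counts(small_truth, s), reference)
        for s in samples
    }
    matrix = build_variant_matrix(call_sets, reference)
    labels = dict(zip(small_truth.samples["sample"], small_truth.samples["type"]))
    counts = aggregate_counts(matrix, labels)
    totals = variant_count_totals(counts)
    n_truth = len(small_truth.differential_loci)
    # every planted differential locus is variant in type 2 and exclusive
    assert totals["total"] == n_truth
    assert totals["type2_exclusive"] == n_truth
    assert totals["type1_vs_ref"] == 0
    truth_classes = (
        small_truth.differential_loci["variant_class"].value_counts().to_dict()
    )
    got_classes = (
        counts.groupby("variant_class")["total"].sum().to_dict()
    )
    assert got_classes == truth_classes


def test_variant_matrix_tsv_round_trips(small_truth, tmp_path):
    reference = small_truth.reference_sequences()
    call_sets = {
        s: call_variants(forge.simulate_allele_counts(small_truth, s), reference)
        for s in ("T1_01", "T2_01")
    }
    matrix = build_variant_matrix(call_sets, reference)
    path = tmp_path / "m.tsv"
    variants.write_variant_matrix_tsv(matrix, path)
    back = variants.read_variant_matrix_tsv(path)
    assert back.samples == matrix.samples
    assert back.loci == matrix.loci
    assert back.reference_alleles == matrix.reference_alleles
    for s in matrix.samples:
        assert back.sample_alleles(s) == matrix.sample_alleles(s)


def test_empty_matrix_aggregates_to_empty_table():
    m = VariantMatrix([], [], [], [], {})
    counts = aggregate_counts(m, {})
    assert len(counts) == 0
    assert set(variant_count_totals(counts).values()) == {0}
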