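"""Repeat finding, recombination conformations, junction support,
copy-number segmentation, and end-taper detection."""

import numpy as np
import pytest

from mitopop import forge
from mitopop.core import Genome, Molecule, revcomp
from mitopop.repeats import (
    DepthProfile,
    RepeatPair,
    RepeatPlacement,
    apply_inversion,
    copy_number_segments,
    depth_profile_from_reads,
    detect_linear_taper,
    enumerate_conformations,
    find_long_repeats,
    junction_support,
    parent_junction_signatures,
)

BASES = np.array(list("ACGT"))


def _rand(rng, n):
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _genome(*mols):
    g = Genome()
    for m in mols:
        g.add(m)
    return g


# ---------------------------------------------------------------------------
# find_long_repeats


def test_planted_direct_repeat_found(rng):
    unit = _rand(rng, 1_200)
    seq = _rand(rng, 3_000) + unit + _rand(rng, 4_000) + unit + _rand(rng, 2_000)
    pairs = find_long_repeats([Molecule("m", seq)], min_len=1_000)
    assert len(pairs) == 1
    rp = pairs[0]
    assert rp.orientation == "direct" and rp.length == 1_200
    assert (rp.first.start, rp.first.end) == (3_001, 4_200)
    assert (rp.second.start, rp.second.end) == (8_201, 9_400)


def test_planted_inverted_repeat_found(rng):
    unit = _rand(rng, 1_100)
    seq = _rand(rng, 2_000) + unit + _rand(rng, 3_000) + revcomp(unit) + _rand(rng, 1_000)
    pairs = find_long_repeats([Molecule("m", seq)], min_len=1_000)
    assert len(pairs) == 1
    rp = pairs[0]
    assert rp.orientation == "inverted" and rp.length == 1_100
    assert (rp.first.start, rp.first.end) == (2_001, 3_100)
    assert (rp.second.start, rp.second.end) == (6_101, 7_200)


def test_cross_molecule_repeat_found(rng):
    unit = _rand(rng, 1_500)
    m1 = Molecule("m1", _rand(rng, 2_000) + unit + _rand(rng, 2_000))
    m2 = Molecule("m2", _rand(rng, 500) + unit + _rand(rng, 500))
    pairs = find_long_repeats([m1, m2], min_len=1_000)
    assert len(pairs) == 1
    assert {pairs[0].first.molecule, pairs[0].second.molecule} == {"m1", "m2"}


def test_random_sequence_has_no_long_repeats(rng):
    pairs = find_long_repeats([Molecule("m", _rand(rng, 50_000))], min_len=1_000)
    assert pairs == []


def _oracle_pairs(seq, min_len):
    """All maximal repeated pairs by quadratic dynamic programming."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)

    def match_table(other):
        L = np.zeros((n + 1, len(other) + 1), dtype=np.int32)
        for i in range(n - 1, -1, -1):
            eq = arr[i] == other
            L[i, :-1] = np.where(eq, L[i + 1, 1:] + 1, 0)
        return L

    found = set()
    # direct: seq vs seq, skip the trivial diagonal
    L = match_table(arr)
    for i in range(n):
        for j in range(i + 1, n):
            if L[i, j] >= min_len and (i == 0 or arr[i - 1] != arr[j - 1]):
                ln = int(L[i, j])
                found.add(((i + 1, i + ln), (j + 1, j + ln), "direct"))
    # inverted: seq vs its reverse complement, mapped back
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    L = match_table(rc)
    for i in range(n):
        for j in range(n):
            if L[i, j] >= min_len and (i == 0 or j == 0 or arr[i - 1] != rc[j - 1]):
                ln = int(L[i, j])
                iv1 = (i + 1, i + ln)
                iv2 = (n - (j + ln) + 1, n - j)
                if iv1 == iv2:
                    continue  # palindrome matching itself
                a, b = sorted([iv1, iv2])
                found.add((a, b, "inverted"))
    return found


def test_agrees_with_dp_oracle_on_small_sequences(rng):
    """Exact agreement with an all-pairs substring-matching oracle on
    sequences with planted short repeats."""
    for trial in range(8):
        parts = [_rand(rng, 120)]
        units = [_rand(rng, int(rng.integers(22, 45))) for _ in range(3)]
        for u in units:
            parts += [u, _rand(rng, 60)]
        parts += [revcomp(units[0]), _rand(rng, 80), units[1], _rand(rng, 50)]
        seq = "".join(parts)
        got = {
            (
                (p.first.start, p.first.end),
                (p.second.start, p.second.end),
                p.orientation,
            )
            for p in find_long_repeats([Molecule("m", seq)], min_len=20)
        }
        assert got == _oracle_pairs(seq, 20), f"trial {trial}"


def test_min_len_validated():
    with pytest.raises(ValueError, match="min_len"):
        find_long_repeats([Molecule("m", "ACGT" * 100)], min_len=10)


# ---------------------------------------------------------------------------
# Conformations


def _direct_pair(mol, a1, a2, length):
    return RepeatPair(
        RepeatPlacement(mol, a1, a1 + length - 1, "+"),
        RepeatPlacement(mol, a2, a2 + length - 1, "+"),
        "direct",
        length,
    )


def test_direct_split_reproduces_subgenomic_circle_lengths(rng):
    """A direct pair on a 218 kb circle placed for 135 kb / 83 kb products
    (the classic two-subgenomic-circles arithmetic): product lengths sum
    to the parent exactly, each product retaining one repeat copy."""
    length = 2_000
    seq = _rand(rng, 218_000)
    unit = _rand(rng, length)
    a1, a2 = 10_001, 145_001  # product1 spans a1..a2-1 = 135 kb
    seq = seq[: a1 - 1] + unit + seq[a1 - 1 + length :]
    seq = seq[: a2 - 1] + unit + seq[a2 - 1 + length :]
    genome = _genome(Molecule("m", seq, "circular"))
    rp = _direct_pair("m", a1, a2, length)
    confs = enumerate_conformations(genome, [rp])
    assert len(confs) == 1 and confs[0].event == "split"
    lengths = sorted(len(m) for m in confs[0].molecules)
    assert lengths == [83_000, 135_000]
    assert sum(lengths) == 218_000
    for m in confs[0].molecules:
        assert m.seq.count(unit) == 1  # exactly one repeat copy per product


def test_inversion_flips_intervening_segment_and_is_involution(rng):
    length = 1_000
    unit = _rand(rng, length)
    inner = _rand(rng, 12_846)
    seq = _rand(rng, 5_000) + unit + inner + revcomp(unit) + _rand(rng, 5_000)
    a1 = 5_001
    a2 = a1 + length + 12_846
    rp = RepeatPair(
        RepeatPlacement("m", a1, a1 + length - 1, "+"),
        RepeatPlacement("m", a2, a2 + length - 1, "-"),
        "inverted",
        length,
    )
    genome = _genome(Molecule("m", seq, "circular"))
    confs = enumerate_conformations(genome, [rp])
    assert len(confs) == 1 and confs[0].event == "invert"
    product = confs[0].molecules[0]
    assert len(product) == len(seq)  # length preserved exactly
    assert product.seq[a1 + length - 1 : a2 - 1] == revcomp(inner)
    # involution: applying the event twice restores the parent exactly
    assert apply_inversion(apply_inversion(seq, rp), rp) == seq


def test_direct_pair_across_circles_fuses_them(rng):
    length = 1_000
    unit = _rand(rng, length)
    s1 = _rand(rng, 4_000) + unit + _rand(rng, 3_000)
    s2 = _rand(rng, 2_000) + unit + _rand(rng, 5_000)
    genome = _genome(Molecule("c1", s1, "circular"), Molecule("c2", s2, "circular"))
    rp = RepeatPair(
        RepeatPlacement("c1", 4_001, 4_000 + length, "+"),
        RepeatPlacement("c2", 2_001, 2_000 + length, "+"),
        "direct",
        length,
    )
    confs = enumerate_conformations(genome, [rp])
    assert len(confs) == 1 and confs[0].event == "fuse"
    fused = confs[0].molecules[0]
    assert len(fused) == len(s1) + len(s2)
    assert fused.seq.count(unit) == 2  # both copies retained in the fusion


def test_no_repeats_no_conformations(rng):
    genome = _genome(Molecule("m", _rand(rng, 10_000), "circular"))
    assert enumerate_conformations(genome, []) == []


def test_overlapping_copies_rejected(rng):
    genome = _genome(Molecule("m", _rand(rng, 10_000), "circular"))
    rp = _direct_pair("m", 100, 150, 100)
    with pytest.raises(ValueError, match="overlap"):
        enumerate_conformations(genome, [rp])


def test_length_conservation_on_forge_genome(small_truth):
    genome = small_truth.genomes["type1"]
    reps = find_long_repeats(list(genome), min_len=700)
    for conf in enumerate_conformations(genome, reps):
        assert conf.total_length == genome.total_length


# ---------------------------------------------------------------------------
# Junction support


def _mixture_setup(rng, repeat_len=35):
    """A circle with a short direct repeat, its split products, and the
    competing junction signature sets."""
    seq = _rand(rng, 6_000)
    unit = _rand(rng, repeat_len)
    a1, a2 = 1_001, 3_001
    seq = seq[: a1 - 1] + unit + seq[a1 - 1 + repeat_len :]
    seq = seq[: a2 - 1] + unit + seq[a2 - 1 + repeat_len :]
    parent = Molecule("m", seq, "circular")
    genome = _genome(parent)
    rp = _direct_pair("m", a1, a2, repeat_len)
    conf = enumerate_conformations(genome, [rp])[0]
    signatures = {
        "parent": parent_junction_signatures(genome, rp),
        "split": conf.junctions,
    }
    return parent, conf, signatures


def test_even_mixture_frequencies_within_binomial_ci(rng):
    parent, conf, signatures = _mixture_setup(rng)
    config = forge.ForgeConfig(seed=5, error_rate=0.0, read_length=150)
    reads = forge.simulate_reads(
        {"parent": [parent], "split": conf.molecules},
        config,
        rng,
        weights={"parent": 0.5, "split": 0.5},
        n_reads=20_000,
    )
    support = junction_support(
        reads,
        signatures,
        genome_seqs=[parent.seq] + [m.seq for m in conf.molecules],
    )
    total = sum(s.count for s in support.values())
    assert total > 200, "expected hundreds of spanning reads"
    half_width = 2.576 * np.sqrt(0.25 / total)  # binomial 99% CI
    for s in support.values():
        assert not s.flagged
        assert abs(s.frequency - 0.5) <= half_width + 0.02


def test_rare_conformation_reported_with_raw_counts(rng):
    parent, conf, signatures = _mixture_setup(rng)
    config = forge.ForgeConfig(seed=6, error_rate=0.0, read_length=150)
    reads = forge.simulate_reads(
        {"parent": [parent], "split": conf.molecules},
        config,
        rng,
        weights={"parent": 0.98, "split": 0.02},
        n_reads=20_000,
    )
    support = junction_support(reads, signatures)
    assert support["split"].frequency < 0.06
    assert support["split"].count >= 0  # raw counts always reported
    assert support["parent"].frequency > 0.9


def test_zero_spanning_reads_is_a_no_call(rng):
    _parent, _conf, signatures = _mixture_setup(rng)
    support = junction_support([("r0", "ACGT" * 40)], signatures)
    for s in support.values():
        assert s.count == 0 and s.frequency is None


def test_repetitive_signature_flagged(rng):
    sig = _rand(rng, 80)
    genome_seq = sig + _rand(rng, 500) + sig
    support = junction_support(
        [("r0", sig)], {"c": [sig]}, genome_seqs=[genome_seq]
    )
    assert support["c"].flagged and support["c"].frequency is None


# ---------------------------------------------------------------------------
# Copy number


def test_flat_profile_is_single_copy(rng):
    depth = rng.poisson(100, size=20_000).astype(float)
    segs = copy_number_segments(DepthProfile("m", depth))
    assert len(segs) == 1
    assert (segs[0].start, segs[0].end, segs[0].copy_number) == (1, 20_000, 1)


@pytest.mark.parametrize("copies", [2, 3])
def test_planted_multicopy_region_recovered(rng, copies):
    mol = Molecule("m", "A" * 30_000, "circular")
    config = forge.ForgeConfig(seed=2, coverage=100.0)
    depth = forge.simulate_depth_profile(
        mol, config, rng, copy_regions=[(12_001, 16_000, copies)]
    )
    segs = copy_number_segments(DepthProfile("m", depth), baseline=100.0)
    multi = [s for s in segs if s.copy_number == copies]
    assert len(multi) == 1
    assert abs(multi[0].start - 12_001) <= 501  # within the smoothing window
    assert abs(multi[0].end - 16_000) <= 501


def test_all_zero_profile_rejected():
    with pytest.raises(ValueError, match="all-zero"):
        copy_number_segments(DepthProfile("m", np.zeros(5_000)))


# ---------------------------------------------------------------------------
# Taper


def test_linear_molecule_taper_detected_within_20_percent(rng):
    mol = Molecule("m", "A" * 90_000, "linear")
    config = forge.ForgeConfig(seed=4, coverage=100.0, taper_max=18_000)
    depth = forge.simulate_depth_profile(mol, config, rng)
    result = detect_linear_taper(DepthProfile("m", depth))
    for side in ("left", "right"):
        assert result[side].is_tapered
        assert abs(result[side].taper_length - 18_000) <= 0.2 * 18_000


def test_circular_molecule_cut_shows_no_taper(rng):
    mol = Molecule("m", "A" * 90_000, "circular")
    config = forge.ForgeConfig(seed=4, coverage=100.0)
    depth = forge.simulate_depth_profile(mol, config, rng)  # no ramp
    result = detect_linear_taper(DepthProfile("m", depth))
    assert not result["left"].is_tapered
    assert not result["right"].is_tapered


def test_flat_noiseless_profile_not_tapered():
    result = detect_linear_taper(DepthProfile("m", np.full(90_000, 80.0)))
    assert not result["left"].is_tapered and not result["right"].is_tapered


def test_taper_from_simulated_reads(rng):
    """Read-level route: uniform end truncation produces the linear
    depth ramp; expected depth at distance x from the end is
    coverage * x / taper_max."""
    mol = Molecule("m", _rand(rng, 90_000), "linear")
    config = forge.ForgeConfig(
        seed=9, coverage=30.0, taper_max=18_000, error_rate=0.0
    )
    reads = forge.simulate_reads({"g": [mol]}, config, rng, n_reads=15_000)
    profile = depth_profile_from_reads(reads, mol)
    interior = float(np.median(profile.depth[30_000:60_000]))
    # binned mean depth on the ramp tracks the closed form
    for lo, hi in [(2_000, 4_000), (8_000, 10_000), (14_000, 16_000)]:
        expected = interior * ((lo + hi) / 2) / 18_000
        got = float(profile.depth[lo:hi].mean())
        assert got == pytest.approx(expected, rel=0.25)


def test_read_length_longer_than_shortest_molecule_rejected(rng):
    config = forge.ForgeConfig(seed=1, read_length=500)
    with pytest.raises(ValueError, match="read_length"):
        forge.simulate_reads(
            {"g": [Molecule("m", _rand(rng, 300), "circular")]}, config, rng
        )
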