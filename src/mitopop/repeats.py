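"""Repeat detection, recombination-conformation enumeration, junction
support, copy-number segmentation, and linear-end taper detection.

Plant mitogenomes recombine on long (>1 kb) repeats: a direct pair on one
circle splits it into two subgenomic circles, a direct pair across two
circles fuses them, and an inverted pair flips the intervening segment.
Each such event produces a diagnostic novel sequence junction whose read
support measures the relative abundance of the alternative conformations.
Multi-copy regions and linear molecules leave coverage signatures: integer
depth ratios, and a progressive depth decline toward unprotected ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .core import Genome, Molecule, interval_overlap, merge_intervals, revcomp


# ---------------------------------------------------------------------------
# Repeat pairs


@dataclass(frozen=True)
class RepeatPlacement:
    molecule: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' | '-'


@dataclass(frozen=True)
class RepeatPair:
    """Two identical (or reverse-complementary) placements of a repeat."""

    first: RepeatPlacement
    second: RepeatPlacement
    orientation: str  # 'direct' | 'inverted'
    length: int

    def __post_init__(self):
        if self.first.end - self.first.start != self.second.end - self.second.start:
            raise ValueError("repeat copies must have identical length")


def find_long_repeats(
    molecules: list[Molecule], min_len: int = 1000, k: int = 31
) -> list[RepeatPair]:
    """All maximal exact repeated pairs of length >= min_len.

    Searches within and between molecules, both orientations, using exact
    k-mer seeds merged along alignment diagonals (seed k = min(k,
    min_len), so every qualifying maximal match is fully tiled by seeds
    and needs no extension step).  Repeats spanning a circular origin are
    not reported.
    """
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    k = min(k, min_len)
    pairs: set[RepeatPair] = set()
    for ai, a in enumerate(molecules):
        for bi in range(ai, len(molecules)):
            b = molecules[bi]
            _collect_direct(a, b, ai == bi, k, min_len, pairs)
            _collect_inverted(a, b, ai == bi, k, min_len, pairs)
    return sorted(
        pairs,
        key=lambda p: (-p.length, p.first.molecule, p.first.start, p.second.start),
    )


def _seed_diagonals(query: str, text: str, k: int) -> dict[int, list[tuple[int, int]]]:
    index: dict[str, list[int]] = {}
    for j in range(len(text) - k + 1):
        index.setdefault(text[j : j + k], []).append(j)
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for i in range(len(query) - k + 1):
        for j in index.get(query[i : i + k], ()):
            by_diag.setdefault(j - i, []).append((i + 1, i + k))  # 1-based on query
    return by_diag


def _collect_direct(a, b, same: bool, k: int, min_len: int, pairs: set) -> None:
    for diag, seeds in _seed_diagonals(a.seq, b.seq, k).items():
        if same and diag == 0:
            continue  # trivial self-match
        for qs, qe in merge_intervals(seeds):
            if qe - qs + 1 < min_len:
                continue
            p1 = RepeatPlacement(a.name, qs, qe, "+")
            p2 = RepeatPlacement(b.name, qs + diag, qe + diag, "+")
            if same and (p2.start, p2.end) < (p1.start, p1.end):
                p1, p2 = p2, p1
            pairs.add(RepeatPair(p1, p2, "direct", qe - qs + 1))


def _collect_inverted(a, b, same: bool, k: int, min_len: int, pairs: set) -> None:
    n = len(b.seq)
    for diag, seeds in _seed_diagonals(a.seq, revcomp(b.seq), k).items():
        for qs, qe in merge_intervals(seeds):
            if qe - qs + 1 < min_len:
                continue
            # map the rc-frame interval back to b's forward strand
            ts, te = qs + diag, qe + diag
            p1 = RepeatPlacement(a.name, qs, qe, "+")
            p2 = RepeatPlacement(b.name, n - te + 1, n - ts + 1, "-")
            if same:
                if (p2.start, p2.end) < (p1.start, p1.end):
                    p1, p2 = (
                        RepeatPlacement(b.name, p2.start, p2.end, "+"),
                        RepeatPlacement(a.name, p1.start, p1.end, "-"),
                    )
                if (p1.start, p1.end) == (p2.start, p2.end):
                    continue  # a perfect palindrome matching itself
            pairs.add(RepeatPair(p1, p2, "inverted", qe - qs + 1))


# ---------------------------------------------------------------------------
# Conformations


@dataclass
class Conformation:
    """A molecule set derivable from a genome by one recombination event."""

    name: str
    molecules: list[Molecule]
    event: str  # 'split' | 'fuse' | 'invert'
    repeat: RepeatPair
    junctions: list[str] = field(default_factory=list)  # signature windows

    @property
    def total_length(self) -> int:
        return sum(len(m) for m in self.molecules)


def _window(seq: str, circular: bool, start0: int, end0: int) -> str:
    """seq[start0:end0] with circular wrap (0-based half-open)."""
    n = len(seq)
    if circular:
        doubled = seq + seq
        return doubled[start0 % n : start0 % n + (end0 - start0)]
    return seq[max(0, start0) : end0]


def enumerate_conformations(
    genome: Genome, repeats: list[RepeatPair], anchor: int = 30
) -> list[Conformation]:
    """Depth-1 enumeration of recombination products.

    For each repeat pair, applies the single event its geometry allows:
    direct pair on one circle -> split into two circles (lengths summing
    to the parent, one repeat copy each); direct pair across two circles
    -> one fused circle of summed length; inverted pair on one circle ->
    the same circle with the intervening segment reverse-complemented.

    Each novel junction's signature window spans one full retained repeat
    copy plus `anchor` flanking bases on each side — the shortest window
    that distinguishes the product from the parent (and from the
    parent's opposite strand).  A read can therefore only attest a
    junction when it spans the whole repeat copy, which is why events on
    repeats longer than the read length go unsupported by short reads.
    Overlapping repeat copies are an error; other geometries (events on
    linear molecules) are skipped.
    """
    out: list[Conformation] = []
    for idx, rp in enumerate(repeats):
        f, s = rp.first, rp.second
        if f.molecule == s.molecule and interval_overlap(
            (f.start, f.end), (s.start, s.end)
        ):
            raise ValueError("repeat copies overlap each other")
        same_mol = f.molecule == s.molecule
        mol_f = genome[f.molecule]
        mol_s = genome[s.molecule]
        if rp.orientation == "direct" and same_mol and mol_f.is_circular:
            out.append(_split(genome, rp, idx, anchor))
        elif rp.orientation == "direct" and not same_mol:
            if mol_f.is_circular and mol_s.is_circular:
                out.append(_fuse(genome, rp, idx, anchor))
        elif rp.orientation == "inverted" and same_mol and mol_f.is_circular:
            out.append(_invert(genome, rp, idx, anchor))
    return out


def _split(genome: Genome, rp: RepeatPair, idx: int, anchor: int) -> Conformation:
    mol = genome[rp.first.molecule]
    seq = mol.seq
    a1 = rp.first.start
    a2 = rp.second.start
    rlen = rp.length
    # each product starts with its retained repeat copy
    p1 = seq[a1 - 1 : a2 - 1]
    p2 = seq[a2 - 1 :] + seq[: a1 - 1]
    others = [m for m in genome if m.name != mol.name]
    prods = [
        Molecule(f"{mol.name}_splitA", p1, "circular"),
        Molecule(f"{mol.name}_splitB", p2, "circular"),
    ]
    junctions = [
        _window(p, True, -anchor, rlen + anchor) for p in (p1, p2)
    ]
    return Conformation(
        f"conf{idx}_split", prods + others, "split", rp, junctions
    )


def _fuse(genome: Genome, rp: RepeatPair, idx: int, anchor: int) -> Conformation:
    ma = genome[rp.first.molecule]
    mb = genome[rp.second.molecule]
    rlen = rp.length
    rot_a = ma.seq[rp.first.start - 1 :] + ma.seq[: rp.first.start - 1]
    rot_b = mb.seq[rp.second.start - 1 :] + mb.seq[: rp.second.start - 1]
    fused_seq = rot_a + rot_b  # [R][restA][R][restB]
    fused = Molecule(f"{ma.name}_{mb.name}_fused", fused_seq, "circular")
    others = [m for m in genome if m.name not in (ma.name, mb.name)]
    junctions = [
        _window(fused_seq, True, -anchor, rlen + anchor),
        _window(fused_seq, True, len(rot_a) - anchor, len(rot_a) + rlen + anchor),
    ]
    return Conformation(f"conf{idx}_fuse", [fused] + others, "fuse", rp, junctions)


def _invert(genome: Genome, rp: RepeatPair, idx: int, anchor: int) -> Conformation:
    mol = genome[rp.first.molecule]
    seq = mol.seq
    (a1, b1), (a2, b2) = sorted(
        [(rp.first.start, rp.first.end), (rp.second.start, rp.second.end)]
    )
    inner = seq[b1 : a2 - 1]
    new_seq = seq[:b1] + revcomp(inner) + seq[a2 - 1 :]
    inverted = Molecule(mol.name + "_inv", new_seq, mol.topology)
    others = [m for m in genome if m.name != mol.name]
    circ = mol.is_circular
    junctions = [
        _window(new_seq, circ, a1 - 1 - anchor, b1 + anchor),
        _window(new_seq, circ, a2 - 1 - anchor, b2 + anchor),
    ]
    return Conformation(
        f"conf{idx}_invert", [inverted] + others, "invert", rp, junctions
    )


def parent_junction_signatures(
    genome: Genome, rp: RepeatPair, anchor: int = 30
) -> list[str]:
    """Signature windows of the *unrecombined* arrangement: each repeat
    copy with its parental flanks, for use as the competing junction set
    when measuring conformation frequencies."""
    sigs = []
    for pl in (rp.first, rp.second):
        mol = genome[pl.molecule]
        sigs.append(
            _window(mol.seq, mol.is_circular, pl.start - 1 - anchor, pl.end + anchor)
        )
    return sigs


def apply_inversion(seq: str, rp: RepeatPair) -> str:
    """Reverse-complement the segment between an inverted repeat pair
    (repeat copies stay in place); applying it twice is the identity."""
    (a1, b1), (a2, b2) = sorted(
        [(rp.first.start, rp.first.end), (rp.second.start, rp.second.end)]
    )
    return seq[:b1] + revcomp(seq[b1 : a2 - 1]) + seq[a2 - 1 :]


# ---------------------------------------------------------------------------
# Junction support


@dataclass
class JunctionSupport:
    conformation: str
    count: int
    frequency: float | None  # None: no spanning reads at the locus
    flagged: bool  # signature not unique in the genome; excluded


def junction_support(
    reads: list[tuple[str, str]] | list[str],
    signatures: dict[str, list[str]],
    genome_seqs: list[str] | None = None,
) -> dict[str, JunctionSupport]:
    """Read support for competing junction signatures.

    A read supports a conformation iff it exactly contains one of the
    conformation's signature windows (either strand).  Frequencies are
    support counts normalized over all competing conformations at the
    locus; with zero spanning reads everywhere the frequency is a
    no-call (None).  Signatures occurring more than once in
    `genome_seqs` (including their reverse complement) are flagged and
    excluded from the frequency denominator.
    """
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    flagged: dict[str, bool] = {}
    for name, sigs in signatures.items():
        bad = False
        if genome_seqs is not None:
            for sig in sigs:
                occ = sum(s.count(sig) + s.count(revcomp(sig)) for s in genome_seqs)
                if occ > 1:
                    bad = True
        flagged[name] = bad
    counts = {}
    for name, sigs in signatures.items():
        sigs_both = [s for sig in sigs for s in (sig, revcomp(sig))]
        counts[name] = sum(any(s in read for s in sigs_both) for read in seqs)
    total = sum(c for n, c in counts.items() if not flagged[n])
    out = {}
    for name in signatures:
        freq = None
        if not flagged[name] and total > 0:
            freq = counts[name] / total
        out[name] = JunctionSupport(name, counts[name], freq, flagged[name])
    return out


# ---------------------------------------------------------------------------
# Coverage: copy-number segments and linear-end taper


@dataclass
class DepthProfile:
    molecule: str
    depth: np.ndarray  # reads-per-base, length = molecule length

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise ValueError("depth must be nonnegative")


@dataclass(frozen=True)
class CopySegment:
    start: int  # 1-based inclusive
    end: int
    copy_number: int


def copy_number_segments(
    profile: DepthProfile,
    baseline: float | None = None,
    window: int = 501,
    min_seg: int = 1000,
) -> list[CopySegment]:
    """Integer copy-number segmentation of a depth profile.

    The per-position depth/baseline ratio is smoothed by a running median
    (window `window`), rounded to the nearest positive integer (half-
    integers round away from zero, so a 1.5x ratio flags as multicopy),
    and merged into maximal constant-copy intervals; intervals shorter
    than `min_seg` are discarded.  Baseline defaults to the global median
    depth.
    """
    d = profile.depth
    if not d.any():
        raise ValueError("all-zero depth profile")
    if baseline is None:
        baseline = float(np.median(d))
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    smooth = median_filter(d, size=window, mode="nearest")
    ratio = smooth / baseline
    copies = np.maximum(1, np.floor(ratio + 0.5).astype(int))
    segments: list[CopySegment] = []
    start = 0
    for i in range(1, len(copies) + 1):
        if i == len(copies) or copies[i] != copies[start]:
            if i - start >= min_seg:
                segments.append(CopySegment(start + 1, i, int(copies[start])))
            start = i
    return segments


@dataclass(frozen=True)
class TaperResult:
    end: str  # 'left' | 'right'
    is_tapered: bool
    taper_length: int  # estimated extent of the depth ramp, bp


def detect_linear_taper(
    profile: DepthProfile,
    max_taper: int = 20_000,
    min_taper: int = 2_000,
    window: int = 501,
    reach_frac: float = 0.95,
    end_depth_frac: float = 0.5,
    residual_tol: float = 0.1,
) -> dict[str, TaperResult]:
    """Detect progressive depth decline toward each molecule end.

    For each end the taper extent T is where the smoothed depth first
    recovers to `reach_frac` of the interior median; the end is called
    tapered when T >= min_taper, the depth at the terminus is below
    `end_depth_frac` of the interior median, and an isotonic
    (non-decreasing inward) fit over [0, T] leaves a relative RMS
    residual below `residual_tol` — i.e. the decline is monotone, not
    noise.  Requires molecule length > 4 x max_taper.
    """
    d = profile.depth
    n = len(d)
    if n <= 4 * max_taper:
        raise ValueError("molecule too short for the requested max taper")
    smooth = median_filter(d, size=window, mode="nearest")
    q = n // 4
    interior = float(np.median(smooth[q : n - q]))
    out = {}
    for side in ("left", "right"):
        prof = smooth[:max_taper] if side == "left" else smooth[-max_taper:][::-1]
        above = np.nonzero(prof >= reach_frac * interior)[0]
        t = int(above[0]) if len(above) else max_taper
        tapered = t >= min_taper and prof[0] < end_depth_frac * interior
        if tapered and t > 1:
            iso = _isotonic_increasing(prof[:t])
            rms = float(np.sqrt(np.mean((prof[:t] - iso) ** 2)))
            tapered = rms < residual_tol * interior
        out[side] = TaperResult(side, bool(tapered), t)
    return out


def _isotonic_increasing(y: np.ndarray) -> np.ndarray:
    """Least-squares non-decreasing fit (pool adjacent violators)."""
    y = np.asarray(y, dtype=float)
    level = y.copy()
    weight = np.ones_like(y)
    blocks = []  # (value, weight, count)
    for v in level:
        blocks.append([v, 1.0, 1])
        while len(blocks) > 1 and blocks[-2][0] > blocks[-1][0]:
            v2, w2, c2 = blocks.pop()
            v1, w1, c1 = blocks.pop()
            blocks.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2, c1 + c2])
    fit = np.concatenate([np.full(c, v) for v, _w, c in blocks])
    return fit


def depth_profile_from_reads(
    reads: list[tuple[str, str]], molecule: Molecule
) -> DepthProfile:
    """Depth profile from forge reads (using their start/mol tags)."""
    depth = np.zeros(len(molecule))
    for rid, seq in reads:
        tags = dict(t.split("=", 1) for t in rid.split("|")[1:] if "=" in t)
        if tags.get("mol") != molecule.name:
            continue
        start = int(tags["start"])
        end = start + len(seq) - 1
        if end <= len(molecule):
            depth[start - 1 : end] += 1
        else:  # wrapped read on a circular molecule
            depth[start - 1 :] += 1
            depth[: end - len(molecule)] += 1
    return DepthProfile(molecule.name, depth)
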