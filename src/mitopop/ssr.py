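"""MISA-style detection of perfect microsatellites (SSRs).

Scans for maximal perfect tandem runs of primitive motifs 1-6 bp long.
A run is reported when its number of complete motif repetitions meets the
class minimum; the organelle-genome defaults are 10, 6, 5, 5, 5, 5 for
mono- through hexanucleotide motifs.  Compound/interrupted SSRs are out of
scope; sequences are scanned linearly (no circular wrap-around).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core import revcomp

DEFAULT_MIN_REPEATS = (10, 6, 5, 5, 5, 5)


@dataclass(frozen=True)
class SsrThresholds:
    """Minimum complete repetitions per motif length 1..6."""

    min_repeats: tuple[int, ...] = DEFAULT_MIN_REPEATS

    def __post_init__(self):
        if len(self.min_repeats) != 6 or any(m < 2 for m in self.min_repeats):
            raise ValueError("need six minimum-repeat counts, all >= 2")

    def minimum(self, motif_len: int) -> int:
        return self.min_repeats[motif_len - 1]


@dataclass(frozen=True)
class SsrRecord:
    molecule: str
    start: int  # 1-based inclusive
    end: int
    motif: str  # as observed at `start`
    repeats: int

    @property
    def motif_len(self) -> int:
        return len(self.motif)

    @property
    def total_length(self) -> int:
        return self.end - self.start + 1

    @property
    def canonical_group(self) -> str:
        return canonical_motif(self.motif)


def is_primitive(motif: str) -> bool:
    """True when the motif is not itself a tandem repeat of a shorter one."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """MISA-convention motif group: a motif is merged with all its
    rotations and with the rotations of its reverse complement; displayed
    as e.g. ``A/T``, ``C/G``, ``AT``."""
    rots = {motif[i:] + motif[:i] for i in range(len(motif))}
    rc = revcomp(motif)
    rc_rots = {rc[i:] + rc[:i] for i in range(len(rc))}
    a, b = min(rots), min(rc_rots)
    if a == b or a in rc_rots:
        return min(a, b)
    lo, hi = sorted((a, b))
    return f"{lo}/{hi}"


def _maximal_runs(seq: str, motif_len: int) -> list[tuple[int, int, str]]:
    """All maximal tandem runs of period `motif_len` as 0-based
    (start, n_complete_repeats, motif) with a primitive motif."""
    runs = []
    n = len(seq)
    i = 0
    while i + motif_len <= n:
        j = i + motif_len
        while j < n and seq[j] == seq[j - motif_len]:
            j += 1
        count = (j - i) // motif_len
        if count >= 2:
            motif = seq[i : i + motif_len]
            if is_primitive(motif) and "N" not in motif:
                runs.append((i, count, motif))
            i = j - motif_len + 1  # next window that could start a new run
        else:
            i += 1
    return runs


def find_ssrs(
    sequence: str,
    thresholds: SsrThresholds = SsrThresholds(),
    molecule: str = "seq",
) -> list[SsrRecord]:
    """All qualifying perfect SSRs in a sequence.

    Runs are reported once under their primitive motif with the number of
    complete repetitions.  When two qualifying runs overlap, the longer is
    kept (tie: earlier start).
    """
    sequence = sequence.upper()
    candidates: list[SsrRecord] = []
    for m in range(1, 7):
        for start0, count, motif in _maximal_runs(sequence, m):
            if count >= thresholds.minimum(m):
                candidates.append(
                    SsrRecord(
                        molecule=molecule,
                        start=start0 + 1,
                        end=start0 + m * count,
                        motif=motif,
                        repeats=count,
                    )
                )
    # longest-run preference on overlap; tie broken by earlier start
    candidates.sort(key=lambda r: (-r.total_length, r.start, r.motif_len))
    kept: list[SsrRecord] = []
    for rec in candidates:
        if all(rec.end < k.start or rec.start > k.end for k in kept):
            kept.append(rec)
    return sorted(kept, key=lambda r: (r.molecule, r.start))


def summarize_ssrs(records: list[SsrRecord]) -> dict:
    """Counts by motif length and by canonical motif group."""
    by_len = {m: 0 for m in range(1, 7)}
    by_group: dict[str, int] = {}
    for rec in records:
        by_len[rec.motif_len] += 1
        by_group[rec.canonical_group] = by_group.get(rec.canonical_group, 0) + 1
    return {
        "total": len(records),
        "by_motif_length": by_len,
        "by_group": dict(sorted(by_group.items())),
    }


def write_ssr_tsv(records: list[SsrRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule\tstart\tend\tmotif\trepeats\tlength\tgroup\n")
        for r in records:
            fh.write(
                f"{r.molecule}\t{r.start}\t{r.end}\t{r.motif}\t{r.repeats}"
                f"\t{r.total_length}\t{r.canonical_group}\n"
            )
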