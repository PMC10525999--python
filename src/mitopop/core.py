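"""Core sequence containers shared across the toolkit.

Plant mitochondrial genomes are multipartite: one genome is a set of
autonomous molecules, each either circular or linear.  Everything downstream
(repeat detection, recombination enumeration, coverage analysis) operates on
these containers.  All coordinates exposed at interfaces are 1-based
inclusive; internal slicing uses Python conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

IUPAC_NT = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_sequence(seq: str, name: str = "sequence") -> None:
    bad = set(seq.upper()) - IUPAC_NT
    if bad:
        raise ValueError(
            f"{name} contains non-IUPAC nucleotide characters: {sorted(bad)}"
        )


@dataclass
class Molecule:
    """A named sequence with a topology.

    Parameters
    ----------
    name : str
        Identifier, unique within a genome.
    seq : str
        Uppercase nucleotide sequence.
    topology : {"circular", "linear"}
        Whether the molecule is a ring or has free ends.
    """

    name: str
    seq: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        self.seq = self.seq.upper()
        validate_sequence(self.seq, self.name)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, end: int) -> str:
        """Subsequence for 1-based inclusive [start, end], wrapping the
        origin on circular molecules when end exceeds the length."""
        n = len(self.seq)
        if not (1 <= start <= n):
            raise IndexError(f"start {start} outside {self.name} (length {n})")
        if end < start:
            raise IndexError("end before start")
        if end <= n:
            return self.seq[start - 1 : end]
        if not self.is_circular:
            raise IndexError(f"end {end} beyond linear molecule {self.name}")
        doubled = self.seq + self.seq
        if end - start + 1 > n:
            raise IndexError("requested span longer than the molecule")
        return doubled[start - 1 : end]


@dataclass
class Genome:
    """A set of molecules plus a germplasm-type label."""

    molecules: dict[str, Molecule] = field(default_factory=dict)
    type_label: str = ""

    def add(self, mol: Molecule) -> None:
        if mol.name in self.molecules:
            raise ValueError(f"duplicate molecule name {mol.name!r}")
        self.molecules[mol.name] = mol

    def __getitem__(self, name: str) -> Molecule:
        return self.molecules[name]

    def __iter__(self):
        return iter(self.molecules.values())

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def total_length(self) -> int:
        return sum(len(m) for m in self)


def merge_intervals(
    intervals: list[tuple[int, int]], gap: int = 0
) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals, joining any separated by <= gap."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + gap + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the overlap of two 1-based inclusive intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
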