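"""Origin assignment for variants inside a shared chloroplast-DNA insertion.

A plastid segment inserted into the mitogenome before the split of two
germplasm types leaves four present-day copies of each locus: the
chloroplast and mitochondrial copies of type 1 and of type 2.  Their
Ref/Alt states relative to the type-1 chloroplast reference form a "quad
pattern".  Under the single-ancestral-insertion assumption the four copies
are related by the fixed unrooted quartet

    ((chloro_type1, chloro_type2), (mito_type1, mito_type2))

and Fitch parsimony on that quartet localizes each mutation to the
organelle lineage in which it arose.  A change forced onto the internal
branch cannot be attributed to either organelle (Ambiguous); patterns
needing two changes are reported as Conflict.

Also provides k-mer homology scanning to detect the insertions themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .core import Molecule
from .homology import find_homology_segments

__all__ = [
    "QuadPattern",
    "OriginCall",
    "assign_origin",
    "summarize_origins",
    "find_cp_insertions",
]

# taxon order used throughout: (chloro_t1, mito_t1, chloro_t2, mito_t2)
_TAXA = ("chloro_t1", "mito_t1", "chloro_t2", "mito_t2")
_TERMINAL_BRANCH_ORGANELLE = {
    "chloro_t1": "Chloro",
    "chloro_t2": "Chloro",
    "mito_t1": "Mito",
    "mito_t2": "Mito",
}


@dataclass(frozen=True)
class QuadPattern:
    """Ref/Alt states at one insertion locus, in the order
    (type1-chloro, type1-mito, type2-chloro, type2-mito).

    "Ref" means identical to the type-1 chloroplast reference.  A state
    polymorphic within a type is encoded as Alt and flagged."""

    locus: str
    chloro_t1: str
    mito_t1: str
    chloro_t2: str
    mito_t2: str
    variant_class: str = "SNP"
    polymorphic: bool = False

    def states(self) -> tuple[str, str, str, str]:
        return (self.chloro_t1, self.mito_t1, self.chloro_t2, self.mito_t2)

    def __post_init__(self):
        for s in self.states():
            if s not in ("Ref", "Alt"):
                raise ValueError(f"non-binary state {s!r} at {self.locus}")


@dataclass(frozen=True)
class OriginCall:
    locus: str
    organelle: str  # Mito | Chloro | Ambiguous | Conflict | NoVariant
    branch: str | None  # terminal lineage, when resolvable
    parsimony_score: int
    polymorphic: bool = False


def _quartet_score(states: tuple[str, ...]) -> tuple[int, list[frozenset[str]]]:
    """Minimum number of state changes on the fixed quartet and, for each
    minimum-change internal labelling, the set of branches carrying a
    change.  Branch names: the four taxon names plus 'internal'."""
    c1, m1, c2, m2 = states
    best = None
    solutions = []
    # x joins the chloroplast pair, y the mitochondrial pair
    for x, y in product(("Ref", "Alt"), repeat=2):
        changed = []
        if x != c1:
            changed.append("chloro_t1")
        if x != c2:
            changed.append("chloro_t2")
        if y != m1:
            changed.append("mito_t1")
        if y != m2:
            changed.append("mito_t2")
        if x != y:
            changed.append("internal")
        score = len(changed)
        if best is None or score < best:
            best = score
            solutions = [frozenset(changed)]
        elif score == best:
            solutions.append(frozenset(changed))
    return best, solutions


def assign_origin(pattern: QuadPattern) -> OriginCall:
    """Localize one insertion variant to the lineage where it arose.

    Returns NoVariant for an all-Ref pattern, Mito/Chloro with the
    terminal branch when a unique single change explains the pattern,
    Ambiguous when the single change sits on the internal branch, and
    Conflict when at least two changes are required.
    """
    score, solutions = _quartet_score(pattern.states())
    if score == 0:
        return OriginCall(pattern.locus, "NoVariant", None, 0, pattern.polymorphic)
    if score == 1:
        branches = {next(iter(s)) for s in solutions}
        if branches == {"internal"}:
            return OriginCall(pattern.locus, "Ambiguous", None, 1, pattern.polymorphic)
        if len(branches) == 1:
            br = next(iter(branches))
            return OriginCall(
                pattern.locus,
                _TERMINAL_BRANCH_ORGANELLE[br],
                br,
                1,
                pattern.polymorphic,
            )
        # multiple equally parsimonious placements
        organs = {_TERMINAL_BRANCH_ORGANELLE.get(b, "Ambiguous") for b in branches}
        if organs == {"Mito"} or organs == {"Chloro"}:
            return OriginCall(pattern.locus, organs.pop(), None, 1, pattern.polymorphic)
        return OriginCall(pattern.locus, "Ambiguous", None, 1, pattern.polymorphic)
    return OriginCall(pattern.locus, "Conflict", None, score, pattern.polymorphic)


def summarize_origins(calls: list[OriginCall]) -> dict[str, int]:
    """Tally of Mito / Chloro / Ambiguous / Conflict / NoVariant calls."""
    counts = {"Mito": 0, "Chloro": 0, "Ambiguous": 0, "Conflict": 0, "NoVariant": 0}
    for call in calls:
        counts[call.organelle] += 1
    return counts


# ---------------------------------------------------------------------------
# Insertion detection


@dataclass(frozen=True)
class HomologySegment:
    """A mitogenome interval homologous to a plastome interval."""

    mito_molecule: str
    mito_interval: tuple[int, int]
    plastome_interval: tuple[int, int]
    orientation: str  # 'direct' or 'inverted'
    identity: float
    length: int


def find_cp_insertions(
    mito_molecules: list[Molecule],
    plastome: str,
    min_len: int = 500,
    k: int = 31,
    gap: int = 200,
) -> list[HomologySegment]:
    """Chloroplast-derived segments of the mitogenome.

    K-mer seeded (k=31), chained along diagonals, merged within `gap`,
    reported when the merged span reaches `min_len`; both orientations.
    """
    if min_len < 100:
        raise ValueError("min_len must be >= 100")
    segments = []
    for mol in mito_molecules:
        for hit in find_homology_segments(mol.seq, plastome, k=k, gap=gap, min_len=min_len):
            segments.append(
                HomologySegment(
                    mito_molecule=mol.name,
                    mito_interval=(hit.q_start, hit.q_end),
                    plastome_interval=(hit.t_start, hit.t_end),
                    orientation=hit.orientation,
                    identity=hit.identity,
                    length=hit.q_end - hit.q_start + 1,
                )
            )
    return sorted(segments, key=lambda s: (s.mito_molecule, s.mito_interval))
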