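"""Readers and writers for the pipeline's file formats, plus in-silico PCR.

The pipeline's lingua franca for read evidence is a pileup-style TSV with
per-allele counts split by strand (columns ``molecule  pos  allele  fwd
rev``), derivable from a standard samtools mpileup.  Allele strings follow
pileup conventions: a single base for a match/substitution, ``+SEQ`` for an
insertion anchored after the position, and ``-SEQ`` for a deletion whose
first deleted base is at the position.

All file coordinates are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import IUPAC_NT, Molecule, revcomp

PILEUP_COLUMNS = ["molecule", "pos", "allele", "fwd", "rev"]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, allow_gaps: bool = False) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: uppercase sequence}`` dict.

    Rejects empty files, duplicate identifiers, and characters outside the
    IUPAC nucleotide alphabet (``allow_gaps`` additionally admits ``-``
    for aligned input).
    """
    alphabet = IUPAC_NT | {"-"} if allow_gaps else IUPAC_NT
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(
                f"record {rec.id!r} has non-IUPAC characters: {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_molecules(path, topologies: dict[str, str] | None = None) -> list[Molecule]:
    """Read FASTA into Molecule objects; topology defaults to circular
    unless the record id appears in `topologies`."""
    topologies = topologies or {}
    return [
        Molecule(name, seq, topologies.get(name, "circular"))
        for name, seq in read_fasta(path).items()
    ]


# ---------------------------------------------------------------------------
# Pileup tables


class PileupTable:
    """Per-sample, per-locus allele counts split by strand.

    Wraps a DataFrame with columns ``molecule, pos, allele, fwd, rev``.
    Counts are post-quality-floor: the upstream converter is expected to
    have dropped bases below the Phred cutoff before counting.
    """

    def __init__(self, df: pd.DataFrame, molecule_lengths: dict[str, int] | None = None):
        missing = set(PILEUP_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"pileup table missing columns: {sorted(missing)}")
        df = df[PILEUP_COLUMNS].copy()
        df["pos"] = df["pos"].astype(int)
        df["fwd"] = df["fwd"].astype(int)
        df["rev"] = df["rev"].astype(int)
        if (df["fwd"] < 0).any() or (df["rev"] < 0).any():
            raise ValueError("negative allele counts")
        if df.duplicated(subset=["molecule", "pos", "allele"]).any():
            raise ValueError("duplicate (molecule, pos, allele) rows")
        if (df["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        if molecule_lengths is not None:
            for mol, sub in df.groupby("molecule"):
                if mol not in molecule_lengths:
                    raise ValueError(f"unknown molecule {mol!r}")
                if (sub["pos"] > molecule_lengths[mol]).any():
                    raise ValueError(f"position beyond length of {mol!r}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def depth(self, molecule: str, pos: int) -> int:
        sub = self.df[(self.df["molecule"] == molecule) & (self.df["pos"] == pos)]
        return int((sub["fwd"] + sub["rev"]).sum())

    def loci(self):
        """Iterate (molecule, pos, sub-frame) over loci in sorted order."""
        for key, sub in self.df.groupby(["molecule", "pos"], sort=True):
            yield key[0], key[1], sub

    def __eq__(self, other) -> bool:
        if not isinstance(other, PileupTable):
            return NotImplemented
        a = self.df.sort_values(["molecule", "pos", "allele"]).reset_index(drop=True)
        b = other.df.sort_values(["molecule", "pos", "allele"]).reset_index(drop=True)
        return a.equals(b)


def read_pileup_tsv(path, molecule_lengths: dict[str, int] | None = None) -> PileupTable:
    df = pd.read_csv(path, sep="\t", dtype={"molecule": str, "allele": str})
    return PileupTable(df, molecule_lengths)


def write_pileup_tsv(table: PileupTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele-string helpers (shared with the variant caller)


def allele_class(allele: str) -> str:
    """Classify a pileup-style allele string as SNP, INS or DEL."""
    if allele.startswith("+"):
        return "INS"
    if allele.startswith("-"):
        return "DEL"
    return "SNP"


def render_allele(allele: str, reference: str) -> str:
    """Render one variant-matrix cell.

    Insertions show the first two inserted bases, deletions the letter
    ``D``, and cells identical to the reference a dash.
    """
    if allele == reference:
        return "-"
    cls = allele_class(allele)
    if cls == "INS":
        return allele[1:3]
    if cls == "DEL":
        return "D"
    return allele


def render_variant_matrix(matrix) -> str:
    """Text rendering of a samples x differential-loci allele matrix.

    The first row carries the reference alleles; sample rows show dashes
    where they match the reference.  `matrix` is a
    :class:`mitopop.variants.VariantMatrix`.
    """
    loci = matrix.loci
    header = ["sample"] + [f"{m}:{p}" for m, p, _cls in loci]
    lines = ["\t".join(header)]
    ref_row = ["REF"] + [
        ref if allele_class(ref) == "SNP" else render_allele(ref, "")
        for ref in matrix.reference_alleles
    ]
    lines.append("\t".join(ref_row))
    for sample in matrix.samples:
        cells = [sample]
        for j, ref in enumerate(matrix.reference_alleles):
            allele = matrix.cell(sample, j)
            cells.append("." if allele is None else render_allele(allele, ref))
        lines.append("\t".join(cells))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# In-silico PCR


@dataclass(frozen=True)
class PcrProduct:
    """One predicted amplicon.

    `start`/`end` are 1-based inclusive and include both primer
    footprints; on circular templates a product spanning the origin keeps
    an unwrapped `end` greater than the template length so that
    ``length == end - start + 1`` always holds.
    """

    template: str
    start: int
    end: int
    length: int
    fwd_strand: str  # strand the forward primer anneals to: '+' or '-'

    def __post_init__(self):
        assert self.length == self.end - self.start + 1


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def insilico_pcr(
    template: Molecule | tuple[str, str, str],
    fwd: str,
    rev: str,
    max_product: int = 20_000,
) -> list[PcrProduct]:
    """Predict PCR products by exact primer matching.

    The forward primer is matched as-is and the reverse primer as its
    reverse complement, on both strands; no mismatches and no
    IUPAC-degenerate expansion.  Circular templates are searched across
    the origin.  Returns an empty list when no product forms.
    """
    if isinstance(template, tuple):
        template = Molecule(*template)
    fwd, rev = fwd.upper(), rev.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    n = len(template.seq)
    search_seq = template.seq + template.seq if template.is_circular else template.seq
    limit = min(max_product, n) if template.is_circular else max_product

    products: set[PcrProduct] = set()
    for f_primer, r_primer, strand in ((fwd, rev, "+"), (rev, fwd, "-")):
        f_sites = _find_all(search_seq, f_primer)
        r_sites = _find_all(search_seq, revcomp(r_primer))
        for i in f_sites:
            if i >= n:  # anchor each product at a start inside one period
                continue
            for j in r_sites:
                end = j + len(r_primer)  # 0-based exclusive
                length = end - i
                if length < max(len(f_primer), len(r_primer)) or length > limit:
                    continue
                products.add(PcrProduct(template.name, i + 1, end, length, strand))
    return sorted(products, key=lambda p: (p.start, p.end, p.fwd_strand))
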