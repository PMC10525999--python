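"""Variant and heteroplasmy calling from allele-count tables, germplasm
typing, and population-level aggregation.

The caller consumes per-sample pileup tables whose counts have already
passed a per-base quality floor (Phred > 20 by default, enforced by the
pileup converter).  Heteroplasmy — the coexistence of two organelle
haplotypes in one individual — is recorded at a locus when a minor allele
reaches a frequency threshold (default 2% of quality-passing depth) and is
seen on both strands, and the locus is not masked as homologous to the
plastome or nuclear decoys.  These filters suppress sequencing error and
strand bias, and the mask keeps reads from look-alike regions in other
compartments from masquerading as organelle heteroplasmy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Molecule, merge_intervals
from .homology import homologous_query_intervals
from .io import PileupTable, allele_class


# ---------------------------------------------------------------------------
# Parameters and result containers


@dataclass
class HetFilterParams:
    """Filters for recording a minor allele as heteroplasmy."""

    min_minor_freq: float = 0.02
    min_phred: int = 20  # applied upstream, at count time
    require_both_strands: bool = True
    mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.min_minor_freq < 0.5:
            raise ValueError("min_minor_freq must be in (0, 0.5)")

    def in_mask(self, molecule: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.mask.get(molecule, ()))


@dataclass(frozen=True)
class VariantCall:
    molecule: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str  # SNP | INS | DEL


@dataclass
class VariantCallSet:
    calls: list[VariantCall]
    nocalls: list[tuple[str, int]]  # loci below min_depth (incl. zero depth)


@dataclass(frozen=True)
class HeteroplasmyRecord:
    molecule: str
    pos: int
    major_allele: str
    major_freq: float
    minor_allele: str
    minor_freq: float
    minor_fwd: int
    minor_rev: int


@dataclass(frozen=True)
class GermplasmAssignment:
    sample: str
    assigned_type: str | None  # 'type1' | 'type2' | None (unassigned)
    type2_fraction: float | None
    marker_present: bool | None
    discordant: bool
    het_median_minor_freq: float | None


# ---------------------------------------------------------------------------
# Homology mask


def build_homology_mask(
    mito_molecules: list[Molecule],
    plastome: str | None,
    decoys: list[str] | None = None,
    min_len: int = 500,
    k: int = 31,
    gap: int = 200,
    keep_intervals: dict[str, list[tuple[int, int]]] | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Mitogenome intervals homologous to the plastome or nuclear decoys.

    `keep_intervals` (e.g. the registered chloroplast-insertion interval,
    which is analysed rather than masked) are subtracted from the mask.
    """
    targets = ([] if plastome is None else [plastome]) + list(decoys or [])
    keep_intervals = keep_intervals or {}
    mask: dict[str, list[tuple[int, int]]] = {}
    for mol in mito_molecules:
        ivs = homologous_query_intervals(mol.seq, targets, k=k, gap=gap, min_len=min_len)
        kept: list[tuple[int, int]] = []
        for s, e in ivs:
            pieces = [(s, e)]
            for ks, ke in keep_intervals.get(mol.name, ()):
                nxt = []
                for ps, pe in pieces:
                    if ke < ps or ks > pe:
                        nxt.append((ps, pe))
                        continue
                    if ps < ks:
                        nxt.append((ps, ks - 1))
                    if pe > ke:
                        nxt.append((ke + 1, pe))
                pieces = nxt
            kept.extend(pieces)
        if kept:
            mask[mol.name] = merge_intervals(kept)
    return mask


# ---------------------------------------------------------------------------
# Calling


def call_variants(
    pileup: PileupTable,
    reference: dict[str, str],
    min_depth: int = 10,
) -> VariantCallSet:
    """Call a variant wherever the sample's majority allele differs from
    the reference base.  Loci below `min_depth` are no-calls, recorded
    separately from reference matches."""
    calls: list[VariantCall] = []
    nocalls: list[tuple[str, int]] = []
    for mol, pos, sub in pileup.loci():
        depth = int((sub["fwd"] + sub["rev"]).sum())
        if depth < min_depth:
            nocalls.append((mol, pos))
            continue
        counts = (sub["fwd"] + sub["rev"]).to_numpy()
        alleles = sub["allele"].to_numpy()
        # count ties broken by lexicographically smallest allele
        major = min(alleles[counts == counts.max()])
        ref = reference[mol][pos - 1]
        if major != ref:
            calls.append(VariantCall(mol, pos, ref, major, allele_class(major)))
    return VariantCallSet(calls, nocalls)


def call_heteroplasmy(
    pileup: PileupTable,
    params: HetFilterParams | None = None,
) -> list[HeteroplasmyRecord]:
    """Record minor alleles passing the frequency, strand-presence and
    mask filters.  One record per qualifying minor allele."""
    params = params or HetFilterParams()
    records: list[HeteroplasmyRecord] = []
    for mol, pos, sub in pileup.loci():
        if params.in_mask(mol, pos):
            continue
        totals = (sub["fwd"] + sub["rev"]).to_numpy()
        depth = int(totals.sum())
        if depth == 0:
            continue
        alleles = sub["allele"].to_numpy()
        order = sorted(range(len(alleles)), key=lambda i: (-totals[i], alleles[i]))
        major_i = order[0]
        major_allele = alleles[major_i]
        major_freq = totals[major_i] / depth
        for i in order[1:]:
            freq = totals[i] / depth
            if freq < params.min_minor_freq:
                continue
            fwd = int(sub["fwd"].iloc[i])
            rev = int(sub["rev"].iloc[i])
            if params.require_both_strands and (fwd < 1 or rev < 1):
                continue
            records.append(
                HeteroplasmyRecord(
                    mol, pos, major_allele, major_freq,
                    sub["allele"].iloc[i], freq, fwd, rev,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Variant matrix


class VariantMatrix:
    """Samples x differential-loci matrix of majority alleles.

    Cells hold pileup-style allele strings; ``None`` marks a no-call.
    Locus metadata rows are ``(molecule, pos, variant_class)``; the class
    is that of the locus's alternate allele.
    """

    def __init__(
        self,
        samples: list[str],
        loci: list[tuple[str, int, str]],
        reference_alleles: list[str],
        alt_alleles: list[str],
        cells: dict[str, list[str | None]],
    ):
        if len(loci) != len(reference_alleles) or len(loci) != len(alt_alleles):
            raise ValueError("loci and allele lists must align")
        self.samples = list(samples)
        self.loci = list(loci)
        self.reference_alleles = list(reference_alleles)
        self.alt_alleles = list(alt_alleles)
        self._cells = {s: list(cells[s]) for s in samples}

    def cell(self, sample: str, locus_index: int) -> str | None:
        return self._cells[sample][locus_index]

    def sample_alleles(self, sample: str) -> list[str | None]:
        return list(self._cells[sample])

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def build_variant_matrix(
    calls_by_sample: dict[str, VariantCallSet],
    reference: dict[str, str],
) -> VariantMatrix:
    """Assemble the population variant matrix from per-sample call sets.

    The locus set is the union of variant loci across samples; a sample
    with no call at a locus and no no-call record there is taken as
    reference-matching.
    """
    locus_info: dict[tuple[str, int], VariantCall] = {}
    for cs in calls_by_sample.values():
        for c in cs.calls:
            locus_info.setdefault((c.molecule, c.pos), c)
    keys = sorted(locus_info)
    loci = [(m, p, locus_info[(m, p)].variant_class) for m, p in keys]
    refs = [locus_info[k].ref_allele for k in keys]
    alts = [locus_info[k].alt_allele for k in keys]
    samples = sorted(calls_by_sample)
    cells: dict[str, list[str | None]] = {}
    for s in samples:
        cs = calls_by_sample[s]
        by_locus = {(c.molecule, c.pos): c.alt_allele for c in cs.calls}
        nocall = set(cs.nocalls)
        cells[s] = [
            None if k in nocall else by_locus.get(k, locus_info[k].ref_allele)
            for k in keys
        ]
    return VariantMatrix(samples, loci, refs, alts, cells)


def write_variant_matrix_tsv(matrix: VariantMatrix, path) -> None:
    """Lossless TSV of the matrix: locus metadata columns followed by one
    raw-allele column per sample ('.' marks a no-call)."""
    with open(path, "w") as fh:
        fh.write(
            "molecule\tpos\tvariant_class\tref\talt\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j, (mol, pos, cls) in enumerate(matrix.loci):
            cells = [
                matrix.cell(s, j) if matrix.cell(s, j) is not None else "."
                for s in matrix.samples
            ]
            fh.write(
                f"{mol}\t{pos}\t{cls}\t{matrix.reference_alleles[j]}"
                f"\t{matrix.alt_alleles[j]}\t" + "\t".join(cells) + "\n"
            )


def read_variant_matrix_tsv(path) -> VariantMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta = ["molecule", "pos", "variant_class", "ref", "alt"]
    samples = [c for c in df.columns if c not in meta]
    loci = [
        (r.molecule, int(r.pos), r.variant_class) for r in df.itertuples()
    ]
    cells = {
        s: [None if v == "." else v for v in df[s]] for s in samples
    }
    return VariantMatrix(samples, loci, list(df["ref"]), list(df["alt"]), cells)


# ---------------------------------------------------------------------------
# Germplasm typing


def type_samples(
    matrix: VariantMatrix,
    type_alleles: list[tuple[str, str]],
    marker_depth: dict[str, float] | None = None,
    genome_median_depth: dict[str, float] | None = None,
    het_summary: dict[str, float] | None = None,
    marker_depth_ratio: float = 0.5,
) -> list[GermplasmAssignment]:
    """Assign each sample to germplasm type 1 or 2.

    The vote at each differential locus compares the sample's majority
    allele with the two type alleles; the assignment is the majority over
    covered loci.  Independently, `marker_present` flags whether mean read
    depth over the type-2-exclusive marker fragment reaches
    `marker_depth_ratio` times the sample's genome-median depth.  A
    discordance between the vote and the marker flag is reported, never
    silently resolved.
    """
    if len(type_alleles) != matrix.n_loci:
        raise ValueError("need one (type1, type2) allele pair per locus")
    out = []
    for sample in matrix.samples:
        alleles = matrix.sample_alleles(sample)
        votes2 = n_typed = 0
        for allele, (a1, a2) in zip(alleles, type_alleles):
            if allele is None:
                continue
            if allele == a2:
                votes2 += 1
                n_typed += 1
            elif allele == a1:
                n_typed += 1
        marker = None
        if marker_depth is not None and sample in marker_depth:
            med = (genome_median_depth or {}).get(sample, 0.0)
            marker = marker_depth[sample] >= marker_depth_ratio * med and med > 0
        if n_typed == 0:
            out.append(
                GermplasmAssignment(sample, None, None, marker, False,
                                    (het_summary or {}).get(sample))
            )
            continue
        frac2 = votes2 / n_typed
        assigned = "type2" if frac2 > 0.5 else "type1"
        discordant = marker is not None and marker != (assigned == "type2")
        out.append(
            GermplasmAssignment(
                sample, assigned, frac2, marker, discordant,
                (het_summary or {}).get(sample),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Population aggregation


def aggregate_counts(
    matrix: VariantMatrix,
    type_labels: dict[str, str],
) -> pd.DataFrame:
    """Per-chromosome, per-class variant counts with exclusivity.

    For each locus the alternate allele is checked for presence (as the
    majority allele) in samples of each type.  A variant is
    type-exclusive when present in at least one sample of that type and
    in no sample of the other.  The `total` column counts distinct
    variant loci, which can be variant against the reference in both
    types at once.
    """
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for j, (mol, _pos, cls) in enumerate(matrix.loci):
        alt = matrix.alt_alleles[j]
        present = {"type1": False, "type2": False}
        for s in matrix.samples:
            if matrix.cell(s, j) == alt:
                present[type_labels[s]] = True
        key = (mol, cls)
        r = rows.setdefault(
            key,
            {"type2_vs_ref": 0, "type2_exclusive": 0,
             "type1_vs_ref": 0, "type1_exclusive": 0, "total": 0},
        )
        if present["type2"]:
            r["type2_vs_ref"] += 1
            if not present["type1"]:
                r["type2_exclusive"] += 1
        if present["type1"]:
            r["type1_vs_ref"] += 1
            if not present["type2"]:
                r["type1_exclusive"] += 1
        if present["type1"] or present["type2"]:
            r["total"] += 1
    records = [
        {"chromosome": mol, "variant_class": cls, **r}
        for (mol, cls), r in sorted(rows.items())
    ]
    columns = ["chromosome", "variant_class", "type2_vs_ref", "type2_exclusive",
               "type1_vs_ref", "type1_exclusive", "total"]
    return pd.DataFrame(records, columns=columns)


def variant_count_totals(counts: pd.DataFrame) -> dict[str, int]:
    """Grand totals of an aggregate table: distinct variant loci overall
    and the type-exclusive tallies."""
    return {
        "total": int(counts["total"].sum()),
        "type2_vs_ref": int(counts["type2_vs_ref"].sum()),
        "type1_vs_ref": int(counts["type1_vs_ref"].sum()),
        "type2_exclusive": int(counts["type2_exclusive"].sum()),
        "type1_exclusive": int(counts["type1_exclusive"].sum()),
    }
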