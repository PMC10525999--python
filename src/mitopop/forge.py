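"""Synthetic multipartite organelle genomes with known ground truth.

The forge builds a two-germplasm population modelled on the marama-bean
study system: a type 1 reference mitogenome and a structurally diverged
type 2 genome that share long repeats and a multi-kilobase chloroplast
insertion, differ at a configurable set of SNP/insertion/deletion loci,
and carry a type-2-exclusive marker fragment.  It then emits the
sequencing summaries the analysis pipeline consumes — per-locus strand-
split allele counts, reads, and depth profiles — so every downstream stage
can be tested against a recorded truth table without external data.

Randomness: one seeded generator drives genome construction; per-sample
sub-streams are derived from (seed, sample index) so adding samples never
shifts the draws of earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Genome, Molecule, revcomp
from .io import PileupTable

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class RepeatSpec:
    """A planted repeat pair: two placements as (molecule_index, start)
    with 1-based starts; `orientation` direct or inverted (second copy
    written as the reverse complement)."""

    length: int
    orientation: str
    placements: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self):
        if self.orientation not in ("direct", "inverted"):
            raise ValueError("orientation must be direct|inverted")
        if self.length <= 0:
            raise ValueError("repeat length must be positive")


def _default_molecules() -> list[tuple[int, str]]:
    # four molecules sized like the type 2 assembly: three rings + one linear
    return [
        (169_406, "circular"),
        (56_355, "circular"),
        (97_120, "linear"),
        (113_687, "circular"),
    ]


def _default_repeats() -> list[RepeatSpec]:
    return [
        # long direct pair on the large ring (split/fuse substrate)
        RepeatSpec(2_000, "direct", ((0, 20_000), (0, 120_000))),
        # inverted pair flanking a 12,846 bp segment (inversion substrate)
        RepeatSpec(1_500, "inverted", ((0, 40_000), (0, 55_846))),
        # shared repeat between the linear molecule and another ring
        # (double-copy region substrate, sized like contig K1)
        RepeatSpec(4_052, "direct", ((2, 5_000), (3, 50_000))),
    ]


@dataclass
class ForgeConfig:
    seed: int = 0
    molecule_specs: list[tuple[int, str]] = field(default_factory=_default_molecules)
    repeat_specs: list[RepeatSpec] = field(default_factory=_default_repeats)
    plastome_length: int = 160_000
    cp_insert_length: int = 9_798
    cp_insert_molecule: int = 1
    cp_insert_pos: int = 20_000  # insertion point in the mito molecule
    cp_insert_plastome_pos: int = 30_000
    n_insert_branch_variants: int = 20  # arise after the germplasm split
    n_insert_internal_variants: int = 72  # mito-vs-chloro, shared by types
    marker_length: int = 2_108
    marker_molecule: int = 1
    marker_pos: int = 45_000  # insertion point in the type 2 genome
    n_differential_loci: int = 254
    class_proportions: tuple[float, float, float] = (143 / 254, 52 / 254, 59 / 254)
    differential_positions: list[tuple[int, int]] | None = None
    heteroplasmy_fraction: float = 0.04
    het_samples_per_type: tuple[int, int] = (1, 0)
    coverage: float = 100.0
    read_length: int = 150
    error_rate: float = 0.001
    taper_max: int = 18_000
    n_samples_per_type: tuple[int, int] = (45, 39)
    decoy_length: int = 20_000
    decoy_segment_length: int = 5_000
    decoy_divergence: float = 0.01

    def __post_init__(self):
        if isinstance(self.n_samples_per_type, int):
            self.n_samples_per_type = (self.n_samples_per_type,) * 2
        if any(l <= 0 for l, _t in self.molecule_specs):
            raise ValueError("molecule lengths must be positive")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if not 0 <= self.heteroplasmy_fraction < 0.5:
            raise ValueError("heteroplasmy_fraction must be in [0, 0.5)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.error_rate < 0 or self.error_rate >= 1:
            raise ValueError("error_rate must be in [0, 1)")

    def class_counts(self) -> tuple[int, int, int]:
        """SNP/INS/DEL counts by largest-remainder apportionment."""
        n = self.n_differential_loci
        raw = [p * n for p in self.class_proportions]
        counts = [int(x) for x in raw]
        rema = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
        for i in range(n - sum(counts)):
            counts[rema[i % 3]] += 1
        return tuple(counts)

    def sample_ids(self) -> list[str]:
        n1, n2 = self.n_samples_per_type
        return [f"T1_{i + 1:02d}" for i in range(n1)] + [
            f"T2_{i + 1:02d}" for i in range(n2)
        ]


# ---------------------------------------------------------------------------
# Truth container


@dataclass
class SyntheticTruth:
    config: ForgeConfig
    genomes: dict[str, Genome]  # 'type1', 'type2'
    plastomes: dict[str, str]
    decoys: dict[str, str]
    differential_loci: pd.DataFrame  # molecule,pos,variant_class,type1,type2
    repeat_registry: list[dict]
    cp_insert: dict  # mito/plastome intervals (type 1 coordinates)
    insert_variants: pd.DataFrame  # quad-pattern truth at insertion loci
    marker_interval: tuple[str, int, int]  # in type 2 coordinates
    mask_truth: dict[str, list[tuple[int, int]]]  # decoy-homologous intervals
    samples: pd.DataFrame  # sample, type, het_fraction

    def reference_sequences(self) -> dict[str, str]:
        return {m.name: m.seq for m in self.genomes["type1"]}

    def type_alleles(self) -> list[tuple[str, str]]:
        return list(
            zip(self.differential_loci["type1"], self.differential_loci["type2"])
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def _sample_rng(config: ForgeConfig, sample_index: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([config.seed, 7919 + sample_index]))
    )


# ---------------------------------------------------------------------------
# Population forging


def forge_population(config: ForgeConfig) -> SyntheticTruth:
    """Build the two-type synthetic population and its truth tables.

    Deterministic for a fixed seed.  The type 2 genome contains one
    exclusive marker fragment absent from type 1; both genomes embed the
    same ancestral chloroplast insertion, modified by the per-organelle
    mutations recorded in the truth table.  Differential loci are placed
    outside repeat copies, the insertion, and the marker region;
    explicitly supplied positions overlapping a repeat copy are rejected.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 1])))
    names = [f"M{i + 1}" for i in range(len(config.molecule_specs))]
    for spec in config.repeat_specs:
        for mol_i, start in spec.placements:
            if mol_i == config.cp_insert_molecule and (
                start + spec.length - 1 >= config.cp_insert_pos
            ):
                raise ValueError(
                    "repeat placements on the insertion-carrying molecule must "
                    "lie upstream of the insertion point (registry coordinates "
                    "are in the reference frame)"
                )
    seqs = [
        list(_random_seq(rng, length)) for length, _t in config.molecule_specs
    ]

    # plant repeat pairs
    repeat_registry = []
    blocked: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(seqs))}
    for spec in config.repeat_specs:
        unit = _random_seq(rng, spec.length)
        placements = []
        for copy_i, (mol_i, start) in enumerate(spec.placements):
            end = start + spec.length - 1
            if end > len(seqs[mol_i]):
                raise ValueError("repeat placement beyond molecule end")
            written = (
                unit
                if spec.orientation == "direct" or copy_i == 0
                else revcomp(unit)
            )
            seqs[mol_i][start - 1 : end] = list(written)
            strand = "+" if (spec.orientation == "direct" or copy_i == 0) else "-"
            placements.append(
                {"molecule": names[mol_i], "start": start, "end": end, "strand": strand}
            )
            blocked[mol_i].append((start, end))
        repeat_registry.append(
            {
                "length": spec.length,
                "orientation": spec.orientation,
                "placements": placements,
            }
        )

    # plastome and the ancestral chloroplast insertion
    plastome_t1 = _random_seq(rng, config.plastome_length)
    ps = config.cp_insert_plastome_pos
    ancestral_insert = plastome_t1[ps - 1 : ps - 1 + config.cp_insert_length]

    # per-organelle, per-branch mutations inside the insertion
    ins_positions = rng.choice(
        np.arange(config.cp_insert_length),
        size=config.n_insert_branch_variants + config.n_insert_internal_variants,
        replace=False,
    )
    ins_positions.sort()
    branch_choices = ["chloro_t1", "mito_t1", "chloro_t2", "mito_t2"]
    insert_rows = []
    mito_mol = names[config.cp_insert_molecule]
    mp = config.cp_insert_pos
    n_internal = config.n_insert_internal_variants
    internal_set = set(
        rng.choice(ins_positions, size=n_internal, replace=False).tolist()
    )
    for off in ins_positions.tolist():
        ref_base = ancestral_insert[off]
        alt_base = _other_base(rng, ref_base)
        if off in internal_set:
            branch = "internal"
            states = ("Ref", "Alt", "Ref", "Alt")  # mito lineage changed
        else:
            branch = branch_choices[rng.integers(0, 4)]
            states = tuple(
                "Alt" if b == branch else "Ref" for b in branch_choices
            )
        insert_rows.append(
            {
                "mito_molecule": mito_mol,
                "mito_pos": mp + off,  # type 1 mito coordinates
                "plastome_pos": ps + off,
                "insert_offset": off,
                "ref": ref_base,
                "alt": alt_base,
                "branch": branch,
                "chloro_t1": states[0],
                "mito_t1": states[1],
                "chloro_t2": states[2],
                "mito_t2": states[3],
            }
        )
    insert_variants = pd.DataFrame(insert_rows)

    # embed the insertion (type 1 mito version) into the mito molecule
    def insert_version(which: str) -> str:
        s = list(ancestral_insert)
        for r in insert_rows:
            if r[which] == "Alt":
                s[r["insert_offset"]] = r["alt"]
        return "".join(s)

    mito_i = config.cp_insert_molecule
    seqs[mito_i][mp - 1 : mp - 1] = list(insert_version("mito_t1"))
    insert_iv = (mp, mp + config.cp_insert_length - 1)
    blocked[mito_i].append(insert_iv)

    plastome_t2 = list(plastome_t1)
    for r in insert_rows:
        if r["chloro_t2"] == "Alt":
            plastome_t2[r["plastome_pos"] - 1] = r["alt"]
    plastome_t2 = "".join(plastome_t2)

    # differential loci, outside repeats / insertion / marker neighborhood
    n_snp, n_ins, n_del = config.class_counts()
    classes = ["SNP"] * n_snp + ["INS"] * n_ins + ["DEL"] * n_del
    margin = 25
    marker_block = (
        config.marker_pos - margin,
        config.marker_pos + margin,
    )
    blocked_for_loci = {i: list(b) for i, b in blocked.items()}
    blocked_for_loci[config.marker_molecule].append(marker_block)

    def is_blocked(mol_i: int, pos: int) -> bool:
        return any(
            s - margin <= pos <= e + margin for s, e in blocked_for_loci[mol_i]
        )

    if config.differential_positions is not None:
        chosen = list(config.differential_positions)
        if len(chosen) != config.n_differential_loci:
            raise ValueError("differential_positions length mismatch")
        for mol_i, pos in chosen:
            if any(s <= pos <= e for s, e in blocked[mol_i]):
                raise ValueError(
                    f"differential locus M{mol_i + 1}:{pos} overlaps a repeat "
                    "copy or the insertion"
                )
    else:
        lengths = np.array([len(s) for s in seqs], dtype=float)
        chosen = []
        taken = set()
        while len(chosen) < config.n_differential_loci:
            mol_i = int(rng.choice(len(seqs), p=lengths / lengths.sum()))
            pos = int(rng.integers(margin + 1, len(seqs[mol_i]) - margin))
            if (mol_i, pos) in taken or is_blocked(mol_i, pos):
                continue
            # keep indel loci well separated so edits never interact
            if any(m == mol_i and abs(p - pos) <= 12 for m, p in taken):
                continue
            taken.add((mol_i, pos))
            chosen.append((mol_i, pos))
        chosen.sort()

    rng.shuffle(classes)
    loci_rows = []
    for (mol_i, pos), cls in zip(chosen, classes):
        ref_base = seqs[mol_i][pos - 1]
        if cls == "SNP":
            t1, t2 = ref_base, _other_base(rng, ref_base)
        elif cls == "INS":
            t1 = ref_base
            t2 = "+" + _random_seq(rng, int(rng.integers(1, 7)))
        else:
            ndel = int(rng.integers(1, 7))
            deleted = "".join(seqs[mol_i][pos - 1 : pos - 1 + ndel])
            t1, t2 = ref_base, "-" + deleted
        loci_rows.append(
            {
                "molecule": names[mol_i],
                "pos": pos,
                "variant_class": cls,
                "type1": t1,
                "type2": t2,
            }
        )
    differential_loci = (
        pd.DataFrame(
            loci_rows, columns=["molecule", "pos", "variant_class", "type1", "type2"]
        )
        .sort_values(["molecule", "pos"])
        .reset_index(drop=True)
    )

    # type 1 genome
    genome1 = Genome(type_label="type1")
    for name, s, (_l, topo) in zip(names, seqs, config.molecule_specs):
        genome1.add(Molecule(name, "".join(s), topo))

    # type 2 genome: copy, swap insertion variants to the t2 branch, apply
    # differential edits back-to-front, then insert the exclusive marker
    seqs2 = [list(s) for s in seqs]
    for r in insert_rows:
        if r["mito_t2"] != r["mito_t1"]:
            base = r["alt"] if r["mito_t2"] == "Alt" else r["ref"]
            seqs2[mito_i][r["mito_pos"] - 1] = base
    by_mol: dict[str, list[dict]] = {}
    for row in loci_rows:
        by_mol.setdefault(row["molecule"], []).append(row)
    for mol_name, rows in by_mol.items():
        mol_i = names.index(mol_name)
        for row in sorted(rows, key=lambda r: -r["pos"]):
            pos, allele = row["pos"], row["type2"]
            if row["variant_class"] == "SNP":
                seqs2[mol_i][pos - 1] = allele
            elif row["variant_class"] == "INS":
                seqs2[mol_i][pos:pos] = list(allele[1:])
            else:
                del seqs2[mol_i][pos - 1 : pos - 1 + len(allele) - 1]
    marker_seq = _random_seq(rng, config.marker_length)
    mk_i = config.marker_molecule
    # marker coordinates in the edited type 2 molecule
    shift = sum(
        (len(r["type2"]) - 1 if r["variant_class"] == "INS" else 1 - len(r["type2"]))
        for r in by_mol.get(names[mk_i], [])
        if r["pos"] < config.marker_pos
    )
    # the insertion-variant swaps are substitutions: no extra shift
    mk_pos = config.marker_pos + shift
    seqs2[mk_i][mk_pos - 1 : mk_pos - 1] = list(marker_seq)
    genome2 = Genome(type_label="type2")
    for name, s, (_l, topo) in zip(names, seqs2, config.molecule_specs):
        genome2.add(Molecule(name, "".join(s), topo))

    # nuclear decoy: a diverged copy of a mitogenome segment
    seg_start = 70_000 if len(seqs[0]) > 80_000 else 1
    seg_end = min(seg_start + config.decoy_segment_length - 1, len(seqs[0]))
    segment = list(genome1[names[0]].seq[seg_start - 1 : seg_end])
    n_div = int(round(config.decoy_divergence * len(segment)))
    div_pos = rng.choice(len(segment), size=n_div, replace=False)
    for p in div_pos:
        segment[p] = _other_base(rng, segment[p])
    flank = max(0, (config.decoy_length - len(segment)) // 2)
    decoy = _random_seq(rng, flank) + "".join(segment) + _random_seq(rng, flank)
    mask_truth = {names[0]: [(seg_start, seg_end)]}

    n1, n2 = config.n_samples_per_type
    h1, h2 = config.het_samples_per_type
    sample_rows = []
    for i, sid in enumerate(config.sample_ids()):
        stype = "type1" if i < n1 else "type2"
        within = i if stype == "type1" else i - n1
        het = (
            config.heteroplasmy_fraction
            if (stype == "type1" and within < h1) or (stype == "type2" and within < h2)
            else 0.0
        )
        sample_rows.append({"sample": sid, "type": stype, "het_fraction": het})

    return SyntheticTruth(
        config=config,
        genomes={"type1": genome1, "type2": genome2},
        plastomes={"type1": plastome_t1, "type2": plastome_t2},
        decoys={"decoy1": decoy},
        differential_loci=differential_loci,
        repeat_registry=repeat_registry,
        cp_insert={
            "mito_molecule": mito_mol,
            "mito_interval": insert_iv,
            "plastome_interval": (ps, ps + config.cp_insert_length - 1),
        },
        insert_variants=insert_variants,
        marker_interval=(names[mk_i], mk_pos, mk_pos + config.marker_length - 1),
        mask_truth=mask_truth,
        samples=pd.DataFrame(sample_rows),
    )


# ---------------------------------------------------------------------------
# Allele-count simulation


def _split_strand(rng: np.random.Generator, n: int) -> tuple[int, int]:
    f = int(rng.binomial(n, 0.5))
    return f, n - f


def simulate_allele_counts(
    truth: SyntheticTruth,
    sample_id: str,
    config: ForgeConfig | None = None,
    loci: str = "differential",
) -> PileupTable:
    """Strand-split allele counts for one sample, in type 1 (reference)
    coordinates.

    Per-locus depth is Poisson(coverage); at differential loci the
    other-type allele appears with the sample's heteroplasmy fraction
    (binomially), and substitution errors land on random other bases at
    `error_rate`.  ``loci='all'`` emits every reference position (slow;
    meant for small genomes), ``'differential'`` only the truth loci.
    """
    config = config or truth.config
    srow = truth.samples[truth.samples["sample"] == sample_id]
    if srow.empty:
        raise ValueError(f"sample {sample_id!r} not registered")
    stype = srow["type"].iloc[0]
    het = float(srow["het_fraction"].iloc[0])
    sample_index = int(srow.index[0])
    rng = _sample_rng(config, sample_index)

    own_col, other_col = ("type1", "type2") if stype == "type1" else ("type2", "type1")
    rows: list[tuple[str, int, str, int, int]] = []

    def emit(mol: str, pos: int, allele: str, n: int):
        if n > 0:
            f, r = _split_strand(rng, n)
            rows.append((mol, pos, allele, f, r))

    diff = truth.differential_loci
    for rec in diff.itertuples():
        depth = int(rng.poisson(config.coverage))
        n_minor = int(rng.binomial(depth, het)) if het > 0 else 0
        n_own = depth - n_minor
        n_err = int(rng.binomial(n_own, config.error_rate))
        n_own -= n_err
        own = getattr(rec, own_col)
        other = getattr(rec, other_col)
        emit(rec.molecule, rec.pos, own, n_own)
        emit(rec.molecule, rec.pos, other, n_minor)
        ref_base = own if len(own) == 1 else "N"
        err_alleles: dict[str, int] = {}
        for _ in range(n_err):
            b = _other_base(rng, ref_base)
            err_alleles[b] = err_alleles.get(b, 0) + 1
        for b, n in err_alleles.items():
            emit(rec.molecule, rec.pos, b, n)

    if loci == "all":
        diff_keys = {(r.molecule, r.pos) for r in diff.itertuples()}
        for mol in truth.genomes["type1"]:
            depths = rng.poisson(config.coverage, size=len(mol))
            errs = rng.binomial(depths, config.error_rate)
            seq = mol.seq
            for i in range(len(mol)):
                pos = i + 1
                if (mol.name, pos) in diff_keys:
                    continue
                emit(mol.name, pos, seq[i], int(depths[i] - errs[i]))
                for _ in range(int(errs[i])):
                    emit(mol.name, pos, _other_base(rng, seq[i]), 1)
    elif loci != "differential":
        raise ValueError("loci must be 'differential' or 'all'")

    df = pd.DataFrame(rows, columns=["molecule", "pos", "allele", "fwd", "rev"])
    df = (
        df.groupby(["molecule", "pos", "allele"], as_index=False)[["fwd", "rev"]]
        .sum()
    )
    return PileupTable(df)


def simulate_marker_evidence(
    truth: SyntheticTruth, sample_id: str, config: ForgeConfig | None = None
) -> tuple[float, float]:
    """(mean depth over the type-2 marker fragment, genome median depth)
    for one sample.  Type 1 samples cover the marker only through their
    heteroplasmic minor genome."""
    config = config or truth.config
    srow = truth.samples[truth.samples["sample"] == sample_id]
    stype = srow["type"].iloc[0]
    het = float(srow["het_fraction"].iloc[0])
    rng = _sample_rng(config, 100_000 + int(srow.index[0]))
    marker_rate = config.coverage * (1.0 if stype == "type2" else het)
    n = config.marker_length
    marker_mean = float(rng.poisson(marker_rate * n)) / n
    genome_median = float(np.median(rng.poisson(config.coverage, size=2_000)))
    return marker_mean, genome_median


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    molecule_sets: dict[str, list[Molecule]],
    config: ForgeConfig,
    rng: np.random.Generator,
    weights: dict[str, float] | None = None,
    n_reads: int | None = None,
    region: tuple[str, int, int] | None = None,
    junction_positions: dict[str, list[tuple[str, int]]] | None = None,
) -> list[tuple[str, str]]:
    """Uniform shotgun reads from a (mixture of) molecule set(s).

    Each named set is a genome conformation; `weights` give the mixture
    proportions (default equal).  Linear molecules are truncated at each
    end by independent Uniform(0, taper_max) amounts per molecule copy.
    Reads wrap the origin on circular molecules.  Read ids carry the
    conformation of origin and, when the read spans a registered junction
    position of its conformation, a ``junction`` tag.  `region` restricts
    read starts to a (molecule, start, end) window (targeted
    resequencing).  Returns (read_id, sequence) pairs.
    """
    names = list(molecule_sets)
    w = np.array([1.0 if weights is None else weights[n] for n in names], float)
    w = w / w.sum()
    shortest = min(len(m) for ms in molecule_sets.values() for m in ms)
    if config.read_length > shortest:
        raise ValueError("read_length exceeds the shortest molecule")
    if n_reads is None:
        total = sum(len(m) for ms in molecule_sets.values() for m in ms) / len(names)
        n_reads = int(config.coverage * total / config.read_length)

    reads: list[tuple[str, str]] = []
    L = config.read_length
    for ridx in range(n_reads):
        conf = names[rng.choice(len(names), p=w)]
        mols = molecule_sets[conf]
        if region is not None:
            mol = next(m for m in mols if m.name == region[0])
            lo, hi = region[1], min(region[2], len(mol) - (0 if mol.is_circular else L))
            start = int(rng.integers(lo, hi + 1))
        else:
            lens = np.array([len(m) for m in mols], float)
            mol = mols[rng.choice(len(mols), p=lens / lens.sum())]
            if mol.is_circular:
                start = int(rng.integers(1, len(mol) + 1))
            else:
                t_left = int(rng.integers(0, config.taper_max + 1))
                t_right = int(rng.integers(0, config.taper_max + 1))
                lo, hi = 1 + t_left, len(mol) - t_right - L + 1
                if hi < lo:
                    continue  # copy truncated below read length
                start = int(rng.integers(lo, hi + 1))
        if not mol.is_circular and start + L - 1 > len(mol):
            continue
        seq = mol.fetch(start, start + L - 1)
        if config.error_rate > 0:
            n_err = rng.binomial(L, config.error_rate)
            if n_err:
                seq = list(seq)
                for p in rng.choice(L, size=n_err, replace=False):
                    seq[p] = _other_base(rng, seq[p])
                seq = "".join(seq)
        strand = "+"
        if rng.random() < 0.5:
            seq, strand = revcomp(seq), "-"
        tags = [f"conf={conf}", f"mol={mol.name}", f"start={start}", f"strand={strand}"]
        for jmol, jpos in (junction_positions or {}).get(conf, ()):
            if jmol == mol.name and start < jpos < start + L - 1:
                tags.append(f"junction={jpos}")
        reads.append((f"r{ridx}|" + "|".join(tags), seq))
    return reads


# ---------------------------------------------------------------------------
# Depth-profile simulation


def simulate_depth_profile(
    molecule: Molecule,
    config: ForgeConfig,
    rng: np.random.Generator,
    copy_regions: list[tuple[int, int, int]] | None = None,
    taper: bool | None = None,
) -> np.ndarray:
    """Per-position Poisson read depth for one molecule.

    `copy_regions` lists (start, end, copy_number) intervals whose rate is
    multiplied accordingly.  For linear molecules (or ``taper=True``) the
    expected depth ramps linearly over the first/last `taper_max` bases —
    the closed-form profile of independent Uniform(0, taper_max) end
    truncations per molecule copy.
    """
    n = len(molecule)
    rate = np.full(n, config.coverage, float)
    for s, e, c in copy_regions or ():
        rate[s - 1 : e] *= c
    if taper is None:
        taper = not molecule.is_circular
    if taper:
        t = config.taper_max
        x = np.arange(1, n + 1, dtype=float)
        rate *= np.minimum(1.0, x / t) * np.minimum(1.0, (n - x + 1) / t)
    return rng.poisson(rate).astype(float)
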