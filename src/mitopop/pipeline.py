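"""End-to-end orchestration: forge (or load) -> counts -> calls -> typing
-> insertion-origin assignment -> SSRs -> trees, with a machine-readable
JSON report.

Every threshold actually applied is echoed into the report, and every
reported number is written to a stage artifact (TSV/FASTA/newick) in the
output directory, so a published run's provenance is self-contained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cporigin, forge, io, phylo, repeats, ssr, variants
from .core import Molecule

log = logging.getLogger("mitopop")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of `forge_config` (synthetic mode) or `reference_fasta` +
    `pileup_tsvs` (real-input mode) must be supplied.
    """

    out_dir: str = "mitopop_run"
    forge_config: forge.ForgeConfig | None = None
    # real-input mode
    reference_fasta: str | None = None
    pileup_tsvs: dict[str, str] | None = None  # sample -> path
    plastome_fasta: str | None = None
    decoy_fasta: str | None = None
    # thresholds
    het_params: variants.HetFilterParams = field(
        default_factory=variants.HetFilterParams
    )
    ssr_thresholds: ssr.SsrThresholds = field(default_factory=ssr.SsrThresholds)
    min_depth: int = 10
    repeat_min_len: int = 1000
    mask_min_len: int = 500
    cp_insert_min_len: int = 500
    marker_window: int = 40
    seg_window: int = 501
    seg_min_len: int = 1000

    def __post_init__(self):
        synthetic = self.forge_config is not None
        real = self.reference_fasta is not None or self.pileup_tsvs is not None
        if synthetic == real:
            raise ValueError(
                "supply exactly one of forge_config or real inputs "
                "(reference_fasta + pileup_tsvs)"
            )


def _echo_thresholds(config: RunConfig) -> dict:
    return {
        "het_min_minor_freq": config.het_params.min_minor_freq,
        "het_min_phred": config.het_params.min_phred,
        "het_require_both_strands": config.het_params.require_both_strands,
        "min_depth": config.min_depth,
        "repeat_min_len": config.repeat_min_len,
        "mask_min_len": config.mask_min_len,
        "cp_insert_min_len": config.cp_insert_min_len,
        "marker_window": config.marker_window,
        "ssr_min_repeats": list(config.ssr_thresholds.min_repeats),
        "seg_window": config.seg_window,
        "seg_min_len": config.seg_min_len,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return the JSON-serializable report.

    Synthetic mode forges a two-type population, simulates per-sample
    allele counts, and runs every downstream stage against the recorded
    truth; real-input mode starts from a reference FASTA and per-sample
    pileup TSVs.  Artifacts are written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "mode": "synthetic" if config.forge_config else "real",
        "thresholds": _echo_thresholds(config),
        "stages": {},
    }

    if config.forge_config is not None:
        truth = forge.forge_population(config.forge_config)
        reference = truth.reference_sequences()
        ref_molecules = list(truth.genomes["type1"])
        plastome = truth.plastomes["type1"]
        decoys = list(truth.decoys.values())
        io.write_fasta(reference, out / "reference.fasta")
        io.write_fasta(
            {m.name: m.seq for m in truth.genomes["type2"]}, out / "type2.fasta"
        )
        truth.differential_loci.to_csv(
            out / "truth_differential_loci.tsv", sep="\t", index=False
        )
        truth.samples.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
        sample_ids = list(truth.samples["sample"])
        pileups = {
            s: forge.simulate_allele_counts(truth, s) for s in sample_ids
        }
        marker_evidence = {
            s: forge.simulate_marker_evidence(truth, s) for s in sample_ids
        }
        keep = {truth.cp_insert["mito_molecule"]: [truth.cp_insert["mito_interval"]]}
        report["stages"]["forge"] = {
            "n_samples": len(sample_ids),
            "n_differential_loci": int(len(truth.differential_loci)),
            "seed": config.forge_config.seed,
        }
    else:
        truth = None
        reference = io.read_fasta(config.reference_fasta)
        ref_molecules = [Molecule(n, s) for n, s in reference.items()]
        plastome = None
        if config.plastome_fasta:
            plastome = "".join(io.read_fasta(config.plastome_fasta).values())
        decoys = (
            list(io.read_fasta(config.decoy_fasta).values())
            if config.decoy_fasta
            else []
        )
        lengths = {n: len(s) for n, s in reference.items()}
        pileups = {
            s: io.read_pileup_tsv(p, lengths)
            for s, p in (config.pileup_tsvs or {}).items()
        }
        marker_evidence = {}
        keep = {}

    # homology mask (plastome + nuclear decoys, insertion kept)
    mask = variants.build_homology_mask(
        ref_molecules,
        plastome,
        decoys,
        min_len=config.mask_min_len,
        keep_intervals=keep,
    )
    config.het_params.mask = mask
    with open(out / "homology_mask.tsv", "w") as fh:
        fh.write("molecule\tstart\tend\n")
        for mol, ivs in mask.items():
            for s, e in ivs:
                fh.write(f"{mol}\t{s}\t{e}\n")
    report["stages"]["mask"] = {
        "n_intervals": sum(len(v) for v in mask.values()),
        "masked_bp": sum(e - s + 1 for v in mask.values() for s, e in v),
    }

    # variant and heteroplasmy calling
    call_sets = {
        s: variants.call_variants(p, reference, config.min_depth)
        for s, p in pileups.items()
    }
    het_records = {
        s: variants.call_heteroplasmy(p, config.het_params)
        for s, p in pileups.items()
    }
    het_rows = [
        {
            "sample": s,
            "molecule": r.molecule,
            "pos": r.pos,
            "major_allele": r.major_allele,
            "major_freq": r.major_freq,
            "minor_allele": r.minor_allele,
            "minor_freq": r.minor_freq,
            "minor_fwd": r.minor_fwd,
            "minor_rev": r.minor_rev,
        }
        for s, recs in het_records.items()
        for r in recs
    ]
    pd.DataFrame(
        het_rows,
        columns=[
            "sample", "molecule", "pos", "major_allele", "major_freq",
            "minor_allele", "minor_freq", "minor_fwd", "minor_rev",
        ],
    ).to_csv(out / "heteroplasmy.tsv", sep="\t", index=False)
    matrix = variants.build_variant_matrix(call_sets, reference)
    (out / "variant_matrix.txt").write_text(io.render_variant_matrix(matrix))
    variants.write_variant_matrix_tsv(matrix, out / "variant_matrix.tsv")
    report["stages"]["calls"] = {
        "n_loci": matrix.n_loci,
        "n_heteroplasmy_records": len(het_rows),
    }

    # germplasm typing and aggregation (requires known type alleles)
    if truth is not None:
        het_summary = {}
        diff_keys = {
            (r.molecule, r.pos) for r in truth.differential_loci.itertuples()
        }
        for s, recs in het_records.items():
            freqs = [r.minor_freq for r in recs if (r.molecule, r.pos) in diff_keys]
            het_summary[s] = float(np.median(freqs)) if freqs else 0.0
        assignments = variants.type_samples(
            matrix,
            _matrix_type_alleles(matrix, truth),
            {s: m for s, (m, _g) in marker_evidence.items()},
            {s: g for s, (_m, g) in marker_evidence.items()},
            het_summary,
        )
        adf = pd.DataFrame(
            [
                {
                    "sample": a.sample,
                    "assigned_type": a.assigned_type,
                    "type2_fraction": a.type2_fraction,
                    "marker_present": a.marker_present,
                    "discordant": a.discordant,
                    "het_median_minor_freq": a.het_median_minor_freq,
                }
                for a in assignments
            ]
        )
        adf.to_csv(out / "typing.tsv", sep="\t", index=False)
        truth_types = dict(zip(truth.samples["sample"], truth.samples["type"]))
        accuracy = float(
            np.mean([a.assigned_type == truth_types[a.sample] for a in assignments])
        )
        counts = variants.aggregate_counts(matrix, truth_types)
        counts.to_csv(out / "variant_counts.tsv", sep="\t", index=False)
        totals = variants.variant_count_totals(counts)
        report["stages"]["typing"] = {
            "n_type1": int(sum(a.assigned_type == "type1" for a in assignments)),
            "n_type2": int(sum(a.assigned_type == "type2" for a in assignments)),
            "accuracy_vs_truth": accuracy,
        }
        report["stages"]["aggregate"] = totals

    # repeats and conformations (reference genome)
    reps = repeats.find_long_repeats(ref_molecules, config.repeat_min_len)
    with open(out / "repeats.tsv", "w") as fh:
        fh.write(
            "molecule1\tstart1\tend1\tstrand1\tmolecule2\tstart2\tend2"
            "\tstrand2\torientation\tlength\n"
        )
        for rp in reps:
            fh.write(
                f"{rp.first.molecule}\t{rp.first.start}\t{rp.first.end}"
                f"\t{rp.first.strand}\t{rp.second.molecule}\t{rp.second.start}"
                f"\t{rp.second.end}\t{rp.second.strand}\t{rp.orientation}"
                f"\t{rp.length}\n"
            )
    genome_obj = (
        truth.genomes["type1"]
        if truth is not None
        else _as_genome(ref_molecules)
    )
    conformations = repeats.enumerate_conformations(genome_obj, reps)
    with open(out / "conformations.tsv", "w") as fh:
        fh.write("name\tevent\tn_molecules\ttotal_length\n")
        for c in conformations:
            fh.write(f"{c.name}\t{c.event}\t{len(c.molecules)}\t{c.total_length}\n")
    report["stages"]["structure"] = {
        "n_repeat_pairs": len(reps),
        "n_conformations": len(conformations),
        "length_conserved": all(
            c.total_length == genome_obj.total_length for c in conformations
        ),
    }

    # coverage: copy-number and taper on simulated profiles (synthetic mode)
    if truth is not None:
        rng = np.random.Generator(
            np.random.PCG64(
                np.random.SeedSequence([config.forge_config.seed, 555])
            )
        )
        cn_regions = _shared_repeat_regions(truth)
        profiles = {}
        for mol in ref_molecules:
            profiles[mol.name] = repeats.DepthProfile(
                mol.name,
                forge.simulate_depth_profile(
                    mol,
                    config.forge_config,
                    rng,
                    copy_regions=cn_regions.get(mol.name),
                ),
            )
        seg_rows = []
        for name, prof in profiles.items():
            for seg in repeats.copy_number_segments(
                prof, window=config.seg_window, min_seg=config.seg_min_len
            ):
                seg_rows.append(
                    {"molecule": name, "start": seg.start, "end": seg.end,
                     "copy_number": seg.copy_number}
                )
        pd.DataFrame(seg_rows).to_csv(
            out / "copy_number_segments.tsv", sep="\t", index=False
        )
        taper_rows = []
        for mol in ref_molecules:
            if mol.is_circular or len(mol) <= 4 * 20_000:
                continue
            for side, res in repeats.detect_linear_taper(profiles[mol.name]).items():
                taper_rows.append(
                    {"molecule": mol.name, "end": side,
                     "is_tapered": res.is_tapered, "taper_length": res.taper_length}
                )
        pd.DataFrame(taper_rows).to_csv(out / "taper.tsv", sep="\t", index=False)
        report["stages"]["coverage"] = {
            "n_multicopy_segments": int(
                sum(r["copy_number"] > 1 for r in seg_rows)
            ),
            "tapered_ends": int(sum(r["is_tapered"] for r in taper_rows)),
        }

    # chloroplast insertions and origin assignment
    if plastome is not None:
        segments = cporigin.find_cp_insertions(
            ref_molecules, plastome, min_len=config.cp_insert_min_len
        )
        with open(out / "cp_insertions.tsv", "w") as fh:
            fh.write(
                "mito_molecule\tmito_start\tmito_end\tplastome_start"
                "\tplastome_end\torientation\tidentity\tlength\n"
            )
            for s in segments:
                fh.write(
                    f"{s.mito_molecule}\t{s.mito_interval[0]}\t{s.mito_interval[1]}"
                    f"\t{s.plastome_interval[0]}\t{s.plastome_interval[1]}"
                    f"\t{s.orientation}\t{s.identity:.4f}\t{s.length}\n"
                )
        report["stages"]["cp_insertions"] = {
            "n_segments": len(segments),
            "longest_bp": max((s.length for s in segments), default=0),
        }
    if truth is not None:
        patterns = [
            cporigin.QuadPattern(
                locus=f"{r.mito_molecule}:{r.mito_pos}",
                chloro_t1=r.chloro_t1,
                mito_t1=r.mito_t1,
                chloro_t2=r.chloro_t2,
                mito_t2=r.mito_t2,
            )
            for r in truth.insert_variants.itertuples()
        ]
        calls = [cporigin.assign_origin(p) for p in patterns]
        with open(out / "insertion_origins.tsv", "w") as fh:
            fh.write("locus\torganelle\tbranch\tparsimony_score\n")
            for c in calls:
                fh.write(
                    f"{c.locus}\t{c.organelle}\t{c.branch or '.'}"
                    f"\t{c.parsimony_score}\n"
                )
        report["stages"]["insertion_origins"] = cporigin.summarize_origins(calls)

    # SSR scan of the reference genome
    ssr_records = [
        r
        for mol in ref_molecules
        for r in ssr.find_ssrs(mol.seq, config.ssr_thresholds, molecule=mol.name)
    ]
    ssr.write_ssr_tsv(ssr_records, out / "ssrs.tsv")
    report["stages"]["ssr"] = ssr.summarize_ssrs(ssr_records)

    # marker-chromosome phylogeny
    if matrix.n_loci >= 1 and len(matrix.samples) >= 3:
        chroms = phylo.build_marker_chromosomes(
            matrix, reference, window=config.marker_window, pad=True
        )
        seqs = {s: c.seq for s, c in chroms.items()}
        io.write_fasta(seqs, out / "marker_chromosomes.fasta")
        dm = phylo.jc_distance_matrix(seqs)
        dm.to_tsv(out / "marker_distances.tsv")
        newick = phylo.nj_tree(dm)
        (out / "marker_nj.nwk").write_text(newick + "\n")
        report["stages"]["phylo"] = {
            "n_taxa": len(dm.taxa),
            "marker_length": len(next(iter(seqs.values()))),
        }

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("report written to %s", report_path)
    return report


def _matrix_type_alleles(matrix, truth) -> list[tuple[str, str]]:
    """Truth (type1, type2) alleles aligned to the matrix's locus order."""
    lookup = {
        (r.molecule, r.pos): (r.type1, r.type2)
        for r in truth.differential_loci.itertuples()
    }
    out = []
    for j, (mol, pos, _cls) in enumerate(matrix.loci):
        ref = matrix.reference_alleles[j]
        out.append(lookup.get((mol, pos), (ref, ref)))
    return out


def _shared_repeat_regions(truth) -> dict[str, list[tuple[int, int, int]]]:
    """Copy-number multipliers for repeat copies shared across molecules
    (the double/triple-copy regions a read mapper would collapse)."""
    per_copy: dict[str, list[tuple[int, int, int]]] = {}
    for entry in truth.repeat_registry:
        placements = entry["placements"]
        mols = {p["molecule"] for p in placements}
        if len(mols) < 2:
            continue  # intra-molecular pairs map uniquely at this scale
        for p in placements:
            per_copy.setdefault(p["molecule"], []).append(
                (p["start"], p["end"], len(placements))
            )
    return per_copy


def _as_genome(molecules: list[Molecule]):
    from .core import Genome

    g = Genome()
    for m in molecules:
        g.add(m)
    return g
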