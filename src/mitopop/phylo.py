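"""Marker-chromosome construction, Jukes-Cantor distances, and
neighbor-joining trees.

Population structure is summarized by concatenating, for every sample, a
short reference window (default 40 bp) around each differential locus
with the sample's allele substituted — an "artificial marker chromosome".
Pairwise distances use the Jukes-Cantor correction
``d = -(3/4) ln(1 - (4/3) p)`` and trees are built with the canonical
Saitou-Nei neighbor-joining agglomeration, which recovers the true tree
exactly on additive distance matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io import allele_class

GAP_CHARS = {"-", "N"}


# ---------------------------------------------------------------------------
# Marker chromosomes


@dataclass
class MarkerChromosome:
    """One sample's concatenated marker sequence.

    `pieces` holds one string per (merged) window group, in locus order;
    `provenance` the corresponding (molecule, window_start, window_end,
    loci) tuples on the reference (1-based inclusive, pre-edit bounds).
    """

    sample: str
    pieces: list[str]
    provenance: list[tuple[str, int, int, tuple[int, ...]]]

    @property
    def seq(self) -> str:
        return "".join(self.pieces)


def _window_groups(matrix, reference: dict[str, str], window: int):
    """Group loci whose reference windows overlap; overlapping windows are
    merged once (with a warning) so no reference base is emitted twice."""
    half_left = (window // 2) - 1  # centered: anchor-19 .. anchor+20 for w=40
    groups: list[dict] = []
    merged_any = False
    for j, (mol, pos, _cls) in enumerate(matrix.loci):
        n = len(reference[mol])
        start = max(1, pos - half_left)
        end = min(n, pos + (window - 1 - half_left))
        if groups and groups[-1]["molecule"] == mol and start <= groups[-1]["end"]:
            groups[-1]["end"] = max(groups[-1]["end"], end)
            groups[-1]["loci"].append(j)
            merged_any = True
        else:
            groups.append({"molecule": mol, "start": start, "end": end, "loci": [j]})
    if merged_any:
        warnings.warn("overlapping marker windows merged", stacklevel=3)
    return groups


def _apply_alleles(ref_piece: str, span_start: int, edits) -> str:
    """Apply (pos, allele) edits to a reference window; edits are applied
    right-to-left so earlier coordinates stay valid."""
    s = ref_piece
    for pos, allele in sorted(edits, reverse=True):
        i = pos - span_start  # 0-based within the window
        cls = allele_class(allele)
        if cls == "SNP":
            s = s[:i] + allele + s[i + 1 :]
        elif cls == "INS":
            s = s[: i + 1] + allele[1:] + s[i + 1 :]
        else:  # DEL: remove bases starting at the position, clipped
            ndel = len(allele) - 1
            s = s[:i] + s[i + ndel :]
    return s


def build_marker_chromosomes(
    matrix,
    reference: dict[str, str],
    window: int = 40,
    pad: bool = False,
) -> dict[str, MarkerChromosome]:
    """Per-sample concatenated marker sequences from a variant matrix.

    Each window is the reference sequence of width `window` centered on
    the locus anchor, clipped at molecule ends, with the sample's allele
    substituted: insertions lengthen and deletions shorten the window's
    yield.  A no-call locus contributes an ``N`` at the anchor.  With
    ``pad=True`` every window group is right-padded with ``-`` to its
    maximum length across samples, so all outputs align column-wise.
    """
    groups = _window_groups(matrix, reference, window)
    out: dict[str, list[str]] = {s: [] for s in matrix.samples}
    for g in groups:
        mol, start, end = g["molecule"], g["start"], g["end"]
        ref_piece = reference[mol][start - 1 : end]
        for s in matrix.samples:
            edits = []
            for j in g["loci"]:
                allele = matrix.cell(s, j)
                ref_allele = matrix.reference_alleles[j]
                pos = matrix.loci[j][1]
                if allele is None:
                    edits.append((pos, "N"))
                elif allele != ref_allele:
                    edits.append((pos, allele))
            out[s].append(_apply_alleles(ref_piece, start, edits))
        if pad:
            width = max(len(out[s][-1]) for s in matrix.samples)
            for s in matrix.samples:
                out[s][-1] = out[s][-1].ljust(width, "-")
    prov = [(g["molecule"], g["start"], g["end"], tuple(g["loci"])) for g in groups]
    return {s: MarkerChromosome(s, pieces, prov) for s, pieces in out.items()}


# ---------------------------------------------------------------------------
# Jukes-Cantor distance


def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor distance between two equal-length sequences.

    Sites with a gap (``-``) or ``N`` in either sequence are excluded
    pairwise.  Raises when no sites remain or when the mismatch
    proportion reaches 3/4 (outside the model's domain).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    retained = mismatches = 0
    for a, b in zip(seq_a, seq_b):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        retained += 1
        if a != b:
            mismatches += 1
    if retained == 0:
        raise ValueError("no comparable sites")
    p = mismatches / retained
    if p >= 0.75:
        raise ValueError(f"mismatch proportion {p:.3f} >= 3/4: JC distance undefined")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be nonnegative")
        self.matrix = m

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for t, row in zip(self.taxa, self.matrix):
                fh.write(t + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")


def jc_distance_matrix(seqs: dict[str, str]) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances (vectorized, pairwise gap/N
    deletion; same definition as :func:`jc_distance`)."""
    taxa = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError("sequences must have equal length")
    arr = np.frombuffer("".join(seqs.values()).encode(), dtype=np.uint8)
    arr = arr.reshape(len(taxa), lengths.pop())
    valid = (arr != ord("-")) & (arr != ord("N"))
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        retained = both.sum(axis=1)
        if (retained == 0).any():
            raise ValueError("no comparable sites for some pair")
        mism = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        p = mism / retained
        if (p >= 0.75).any():
            raise ValueError("mismatch proportion >= 3/4: JC distance undefined")
        d = -0.75 * np.log1p(-(4.0 / 3.0) * p)
        m[i, i + 1 :] = d
        m[i + 1 :, i] = d
    return DistanceMatrix(taxa, m)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> str:
    """Unrooted neighbor-joining tree (Saitou-Nei, Q-criterion) in newick.

    Deterministic: at each step the minimal-Q pair with the lowest node
    index pair is joined; the final edge between the last two nodes is
    split evenly to place the (arbitrary) root.  Branch lengths may be
    negative on non-additive inputs, as in the classical algorithm.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.matrix.copy()
    nodes = [f"{t}" for t in dm.taxa]  # newick fragments
    active = list(range(n))
    full = d  # grows as merged nodes are appended
    while len(active) > 2:
        k = len(active)
        sub = full[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(k):
            for b in range(a + 1, k):
                key = (q[a, b], a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        i, j = active[a], active[b]
        dij = full[i, j]
        li = dij / 2 + (r[a] - r[b]) / (2 * (k - 2))
        lj = dij - li
        merged = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        new_row = 0.5 * (full[i, :] + full[j, :] - dij)
        full = np.pad(full, ((0, 1), (0, 1)))
        full[-1, :-1] = new_row
        full[:-1, -1] = new_row
        nodes.append(merged)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]
    i, j = active
    half = full[i, j] / 2
    return f"({nodes[i]}:{half:.10g},{nodes[j]}:{half:.10g});"


# ---------------------------------------------------------------------------
# Alignment concatenation


def concatenate_alignments(
    blocks: dict[str, dict[str, str]],
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate named aligned blocks into one aligned set.

    Within each block all sequences must be equally long.  A taxon
    missing from a block is gap-filled with a warning.  Returns the
    concatenated sequences and a block map of (name, start, end) column
    coordinates (1-based inclusive).
    """
    taxa: list[str] = []
    for block in blocks.values():
        for t in block:
            if t not in taxa:
                taxa.append(t)
    out = {t: [] for t in taxa}
    block_map: list[tuple[str, int, int]] = []
    col = 1
    for name, block in blocks.items():
        lengths = {len(s) for s in block.values()}
        if len(lengths) > 1:
            raise ValueError(f"block {name!r} has unequal sequence lengths")
        width = lengths.pop() if lengths else 0
        for t in taxa:
            if t in block:
                out[t].append(block[t])
            else:
                warnings.warn(f"taxon {t!r} missing from block {name!r}; gap-filled")
                out[t].append("-" * width)
        block_map.append((name, col, col + width - 1))
        col += width
    return {t: "".join(parts) for t, parts in out.items()}, block_map
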