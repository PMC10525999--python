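"""Shared k-mer seeded homology detection.

Used to find chloroplast-derived insertions in the mitogenome and to build
the homology mask that keeps nuclear/plastid look-alike reads out of the
heteroplasmy caller.  Seeds are exact k-mer matches chained along a common
alignment diagonal and merged across gaps, which resolves homologies whose
divergence is substitutional; diverged copies containing indels fragment
into separate segments (adequate at the divergence levels this pipeline
targets, and documented as a limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import merge_intervals, revcomp


@dataclass(frozen=True)
class HomologyHit:
    """One homologous segment; all coordinates 1-based inclusive on the
    forward strands of query and target."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    orientation: str  # 'direct' | 'inverted'
    identity: float


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _chain_one_strand(
    query: str, text: str, k: int, gap: int, min_len: int
) -> list[tuple[int, int, int, int, float]]:
    """Chained segments against one strand of the target, as 0-based
    inclusive (q_start, q_end, t_start, t_end, identity)."""
    index = _kmer_index(text, k)
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for i in range(len(query) - k + 1):
        for j in index.get(query[i : i + k], ()):
            by_diag.setdefault(j - i, []).append((i, i + k - 1))
    out = []
    for diag, seeds in by_diag.items():
        for qs, qe in merge_intervals([(a + 1, b + 1) for a, b in seeds], gap=gap):
            qs0, qe0 = qs - 1, qe - 1
            if qe0 - qs0 + 1 < min_len:
                continue
            ts0, te0 = qs0 + diag, qe0 + diag
            span_q = query[qs0 : qe0 + 1]
            span_t = text[ts0 : te0 + 1]
            matches = sum(a == b for a, b in zip(span_q, span_t))
            out.append((qs0, qe0, ts0, te0, matches / len(span_q)))
    return out


def find_homology_segments(
    query: str,
    target: str,
    k: int = 31,
    gap: int = 200,
    min_len: int = 500,
) -> list[HomologyHit]:
    """Homologous segments between two sequences, both orientations."""
    query, target = query.upper(), target.upper()
    hits: list[HomologyHit] = []
    for qs0, qe0, ts0, te0, ident in _chain_one_strand(query, target, k, gap, min_len):
        hits.append(HomologyHit(qs0 + 1, qe0 + 1, ts0 + 1, te0 + 1, "direct", ident))
    n = len(target)
    target_rc = revcomp(target)
    for qs0, qe0, ts0, te0, ident in _chain_one_strand(query, target_rc, k, gap, min_len):
        # map an interval on the reverse-complemented target back to the
        # forward strand: rc position p covers forward position n-1-p
        hits.append(
            HomologyHit(qs0 + 1, qe0 + 1, n - te0, n - ts0, "inverted", ident)
        )
    hits.sort(key=lambda h: (h.q_start, h.q_end, h.orientation))
    # drop hits fully contained in a longer hit on the same orientation
    kept: list[HomologyHit] = []
    for h in hits:
        if any(
            o.orientation == h.orientation
            and o.q_start <= h.q_start
            and h.q_end <= o.q_end
            and (o.q_end - o.q_start) > (h.q_end - h.q_start)
            for o in hits
        ):
            continue
        kept.append(h)
    return kept


def homologous_query_intervals(
    query: str, targets: list[str], k: int = 31, gap: int = 200, min_len: int = 500
) -> list[tuple[int, int]]:
    """Union of query intervals homologous to any target (1-based)."""
    ivs: list[tuple[int, int]] = []
    for t in targets:
        for h in find_homology_segments(query, t, k=k, gap=gap, min_len=min_len):
            ivs.append((h.q_start, h.q_end))
    return merge_intervals(ivs)
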