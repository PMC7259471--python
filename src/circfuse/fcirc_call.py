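"""f-circRNA calling: back-spliced reads on the reconstructed fusion.

A read crossing a back-splice junction of a circle ``[s, e)`` on the fusion
sequence consists of the circle's *end* followed by the circle's *start* —
its two segments map in reversed (chiastic) order: the left-in-read segment
lies downstream of the right-in-read segment.  Rotating the read at its
split offset restores forward-spliced order, so re-aligning the transformed
read must place both parts forward at the same loci; reads passing this
verification are attributed to an f-circRNA with junction ``(s, e)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from circfuse.align_core import (
    DEFAULT_SCORING,
    ReadAlignment,
    ScoringParams,
    local_align,
    score_min,
    trim_noisy_segment_ends,
    trim_terminal_gap_blocks,
)


@dataclass(frozen=True)
class BackspliceCandidate:
    """A read whose two segments map in chiastic order on the fusion.

    ``donor_seg`` is the matched reference interval of the read's *left*
    part (the back-splice donor side, downstream), ``acceptor_seg`` that of
    the right part (upstream); chiastic order requires
    ``acceptor_seg[0] < donor_seg[0]``.  ``split_offset`` is the in-read
    boundary between the parts.
    """

    read_id: str
    donor_seg: tuple[int, int]
    acceptor_seg: tuple[int, int]
    split_offset: int


@dataclass
class FcircCall:
    """One called fusion-derived circular RNA on a fusion reference."""

    gene5: str
    gene3: str
    circle_start: int
    circle_end: int
    support: int
    spans_fusion: bool
    mate_consistent: bool | None = None


def _best(read: str, ref: str, params: ScoringParams) -> ReadAlignment | None:
    hits = local_align(read, ref, params, strands="+")
    return trim_terminal_gap_blocks(hits[0], ref=ref) if hits else None


def _near_full(aln: ReadAlignment, part_len: int, slack: int) -> bool:
    """Does the alignment explain (nearly) the entire sequence it aligned?"""
    return aln.q_start <= slack and part_len - aln.q_end <= slack


def detect_chiastic(read: str, fusion_ref: str,
                    params: ScoringParams = DEFAULT_SCORING, min_clip: int = 8,
                    read_id: str = "", slack: int = 3,
                    main: ReadAlignment | None = None) -> BackspliceCandidate | None:
    """Split a read's explanation into two chiastically ordered segments.

    The read (in fusion-reference orientation) must align with one large
    soft clip; the clipped fragment is aligned separately and must explain
    itself near-fully (each edge within ``slack`` bases) with a positive
    segment score — a short clipped fragment matching the reference only by
    chance fails this.  A candidate is returned iff the left-in-read segment
    maps strictly downstream of the right-in-read segment.
    """
    if main is None:
        main = _best(read, fusion_ref, params)
    else:
        main = trim_terminal_gap_blocks(main, min_block=min_clip, ref=fusion_ref)
    if main is None or main.score <= 0:
        return None
    L = len(read)
    lead = main.q_start
    tail = L - main.q_end
    if lead >= min_clip and tail <= slack:
        # main explains the right part (acceptor); its junction-facing left
        # end is cleaned first so the clipped prefix keeps all donor bases
        main_t = trim_noisy_segment_ends(main, fusion_ref, left=True)
        if main_t is None or main_t.q_start < min_clip:
            return None
        split = main_t.q_start
        frag = read[:split]
        frag_aln = _best(frag, fusion_ref, params)
        if frag_aln is None or frag_aln.score <= 0 \
                or not _near_full(frag_aln, len(frag), slack):
            return None
        frag_aln = trim_noisy_segment_ends(frag_aln, fusion_ref, right=True)
        if frag_aln is None:
            return None
        donor = (frag_aln.ref_start, frag_aln.ref_end)
        acceptor = (main_t.ref_start, main_t.ref_end)
    elif tail >= min_clip and lead <= slack:
        # main explains the left part (donor); clean its junction-facing
        # right end, then place the clipped suffix (acceptor)
        main_t = trim_noisy_segment_ends(main, fusion_ref, right=True)
        if main_t is None or len(read) - main_t.q_end < min_clip:
            return None
        split = main_t.q_end
        frag = read[split:]
        frag_aln = _best(frag, fusion_ref, params)
        if frag_aln is None or frag_aln.score <= 0 \
                or not _near_full(frag_aln, len(frag), slack):
            return None
        frag_aln = trim_noisy_segment_ends(frag_aln, fusion_ref, left=True)
        if frag_aln is None:
            return None
        donor = (main_t.ref_start, main_t.ref_end)
        acceptor = (frag_aln.ref_start, frag_aln.ref_end)
    else:
        return None
    if acceptor[0] >= donor[0]:  # forward-ordered or coincident: not back-spliced
        return None
    if donor[1] - donor[0] < min_clip or acceptor[1] - acceptor[0] < min_clip:
        return None
    return BackspliceCandidate(read_id=read_id or main.read_id,
                               donor_seg=donor, acceptor_seg=acceptor,
                               split_offset=split)


def transform_backspliced(read: str, split_offset: int) -> str:
    """Rotate a back-spliced read into forward-spliced segment order.

    Returns ``read[split_offset:] + read[:split_offset]``; applying the
    transform again with ``len(read) - split_offset`` restores the original.
    """
    if not 0 < split_offset < len(read):
        raise ValueError(
            f"split_offset must be in (0, {len(read)}), got {split_offset}")
    return read[split_offset:] + read[:split_offset]


def verify_backsplice(transformed: str, fusion_ref: str,
                      candidate: BackspliceCandidate,
                      params: ScoringParams = DEFAULT_SCORING,
                      locus_tol: int = 2, slack: int = 3) -> tuple[int, int] | None:
    """Re-align a transformed read to confirm the back-splice.

    Verification passes iff both parts of the transformed read align in
    forward order at the same loci as the candidate's segments (start
    positions within ``locus_tol``), each part near-fully explained with a
    positive score, and the combined score reaches ``score_min`` for the
    full read length.  Returns the back-splice junction
    ``(acceptor_start, donor_end)`` (0-based half-open) or ``None``.
    """
    L = len(transformed)
    n_right = L - candidate.split_offset  # length of the original right part
    part1, part2 = transformed[:n_right], transformed[n_right:]
    if not part1 or not part2:
        return None
    al1 = _best(part1, fusion_ref, params)
    al2 = _best(part2, fusion_ref, params)
    if al1 is None or al2 is None:
        return None
    if al1.score <= 0 or al2.score <= 0:
        return None
    if not (_near_full(al1, len(part1), slack) and _near_full(al2, len(part2), slack)):
        return None
    al1 = trim_noisy_segment_ends(al1, fusion_ref, left=True)
    al2 = trim_noisy_segment_ends(al2, fusion_ref, right=True)
    if al1 is None or al2 is None:
        return None
    if al1.ref_start >= al2.ref_start:  # must now be forward-ordered
        return None
    if abs(al1.ref_start - candidate.acceptor_seg[0]) > locus_tol:
        return None
    if abs(al2.ref_start - candidate.donor_seg[0]) > locus_tol:
        return None
    if al1.score + al2.score < score_min(L, params):
        return None
    return (candidate.acceptor_seg[0], candidate.donor_seg[1])


def canonicalize_junction(fusion_ref: str, start: int,
                          end: int) -> tuple[int, int]:
    """Left-most representative of a back-splice junction.

    Sequence homology across the seam makes the seam position ambiguous:
    every ``(start - j, end - j)`` with ``F[start-i] == F[end-i]`` for
    ``i <= j`` describes the same circle (a rotation).  Both the caller and
    any ground truth shift to the left-most rotation.
    """
    while start > 0 and fusion_ref[start - 1] == fusion_ref[end - 1]:
        start -= 1
        end -= 1
    return start, end


def call_fcirc(junctions: Sequence[tuple[int, int]], junction_pos: int,
               min_circ_support: int = 1, cluster_tol: int = 2,
               require_span: bool = True, gene5: str = "", gene3: str = "",
               fusion_len: int | None = None) -> list[FcircCall]:
    """Cluster verified back-splice junctions of one gene pair into calls.

    Junctions whose ends both lie within ``cluster_tol`` bases of the modal
    junction merge into one call at the modal coordinates (ties to the
    smaller start, then end).  Calls below ``min_circ_support`` are dropped.
    ``spans_fusion`` marks circles containing the fusion point
    (``circle_start <= junction_pos < circle_end``); with ``require_span``
    the non-spanning ones are still returned, flagged for exclusion from the
    default f-circRNA table view.
    """
    votes = Counter(junctions)
    remaining = dict(votes)
    calls: list[FcircCall] = []
    while remaining:
        winner = min(remaining, key=lambda k: (-remaining[k], k[0], k[1]))
        support = 0
        for key in list(remaining):
            if abs(key[0] - winner[0]) <= cluster_tol and \
                    abs(key[1] - winner[1]) <= cluster_tol:
                support += remaining.pop(key)
        start, end = winner
        if support < min_circ_support:
            continue
        if fusion_len is not None and end > fusion_len:
            continue
        calls.append(FcircCall(
            gene5=gene5, gene3=gene3, circle_start=start, circle_end=end,
            support=support,
            spans_fusion=start <= junction_pos < end,
        ))
    calls.sort(key=lambda c: (c.circle_start, c.circle_end))
    return calls
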