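"""Linear fusion-transcript calling from paired chiastic clipping signals.

A read that crosses a fusion junction aligns to the two partner genes with
*complementary* soft clips — e.g. ``40M60S`` on the 5' partner and ``40S60M``
on the 3' partner, both on the same strand.  Such a paired chiastic clipping
(PCC) signal pins the junction both in the read (split offset) and on each
gene (per-gene breakpoint).  The exact breakpoint of a gene pair is inferred
from the majority of junction-supporting reads, the fusion sequence is
reconstructed around it, support is recalibrated by re-aligning reads to the
reconstruction, and a Wilcoxon signed-rank test checks whether reads cover
the junction in a balanced way (left vs right fragment lengths).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

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
class PccSignal:
    """One fusion-supporting split read.

    ``bp5`` is 0-based one past the last fused base on the 5' gene (the gene
    whose matched segment *ends* at its breakpoint); ``bp3`` is the 0-based
    first fused base on the 3' gene.  ``split_offset`` is the in-read
    boundary between the two segments, in oriented-read coordinates.
    """

    read_id: str
    gene5: str
    gene3: str
    bp5: int
    bp3: int
    split_offset: int
    strand_consistent: bool = True
    aligned_bases: int = 0


class BreakpointCandidate(NamedTuple):
    bp5: int
    bp3: int
    votes: int


class FusionRef(NamedTuple):
    """A reconstructed fusion reference sequence and its junction position."""

    seq: str
    junction_pos: int


@dataclass
class FusionCall:
    """A reconstructed linear fusion transcript."""

    gene5: str
    gene3: str
    bp5: int
    bp3: int
    fusion_seq: str
    junction_pos: int
    support: int
    balance_p: float = 1.0
    readthrough: bool | None = None
    catalogue_orientation: bool | None = None


# ---------------------------------------------------------------------------
# PCC detection
# ---------------------------------------------------------------------------

def detect_pcc(aln_a: ReadAlignment, aln_b: ReadAlignment, min_clip: int = 8,
               slack: int = 3, refs: Mapping[str, str] | None = None,
               noise_window: int = 12,
               homology_max: int = 12) -> PccSignal | None:
    """Test two alignments of one read for a paired chiastic clipping signal.

    The two CIGARs must be complementary (one ``aM bS``-like, the other
    ``aS bM``-like), both segments at least ``min_clip`` bases, on the same
    strand, against two *different* genes.  The in-read boundaries may leave
    a gap of at most ``slack`` bases or overlap by up to ``homology_max``
    bases — overlap is expected whenever the sequences flanking the junction
    agree by chance (junctional micro-homology), which extends both
    segments across it.  With the reference sequences supplied, each
    segment's junction-facing end is first cut back past any mismatch in
    its terminal ``noise_window`` so that only clean homology extensions
    remain (those are resolved later by breakpoint canonicalization).  The
    signal is canonicalised to the boundary implied by the 5' segment.
    """
    if aln_a.read_id != aln_b.read_id or (aln_a.mate or 0) != (aln_b.mate or 0):
        raise ValueError("PCC detection requires two alignments of the same read")
    if aln_a.is_unmapped or aln_b.is_unmapped:
        return None
    if aln_a.ref_id == aln_b.ref_id or aln_a.ref_id is None or aln_b.ref_id is None:
        return None
    if aln_a.strand != aln_b.strand:
        return None
    read_len = aln_a.cigar.read_len
    if aln_b.cigar.read_len != read_len:
        return None
    aln_a = trim_terminal_gap_blocks(aln_a)
    aln_b = trim_terminal_gap_blocks(aln_b)

    left, right = sorted((aln_a, aln_b), key=lambda a: (a.q_start, -a.q_end))
    if refs is not None:
        if left.ref_id in refs:
            left = trim_noisy_segment_ends(left, refs[left.ref_id],
                                           window=noise_window, right=True)
        if right.ref_id in refs:
            right = trim_noisy_segment_ends(right, refs[right.ref_id],
                                            window=noise_window, left=True)
        if left is None or right is None:
            return None
    if right.q_end <= left.q_end:  # nested, not complementary
        return None
    if left.q_start > slack or read_len - right.q_end > slack:
        return None
    if right.q_start - left.q_end > slack:  # unexplained middle bases
        return None
    if left.q_end - right.q_start > homology_max:  # implausible overlap
        return None
    seg5 = left.q_end - left.q_start
    seg3 = right.q_end - right.q_start
    if seg5 < min_clip or seg3 < min_clip:
        return None

    split = left.q_end
    bp3 = right.ref_start + (split - right.q_start)
    if bp3 < 0:
        return None
    return PccSignal(
        read_id=aln_a.read_id,
        gene5=left.ref_id,
        gene3=right.ref_id,
        bp5=left.ref_end,
        bp3=bp3,
        split_offset=split,
        strand_consistent=True,
        aligned_bases=seg5 + seg3,
    )


# ---------------------------------------------------------------------------
# Breakpoint inference
# ---------------------------------------------------------------------------

def infer_breakpoints(signals: Sequence[PccSignal],
                      cluster_tol: int = 2) -> list[BreakpointCandidate]:
    """Infer breakpoints of one gene pair by majority vote over PCC signals.

    The modal ``(bp5, bp3)`` tuple wins; ties go to the tuple whose
    supporting signals cover more aligned bases, then to the smaller
    ``bp5`` (then ``bp3``).  Tuples within ``cluster_tol`` bases of a winner
    (both coordinates) are absorbed into it — chance single-base matches
    across the junction jitter clip boundaries by a base or two.  Remaining
    distinct tuples repeat the procedure and are returned as secondary
    candidates (potential isoforms), votes included.
    """
    if not signals:
        raise ValueError("need at least one PCC signal")
    votes: Counter[tuple[int, int]] = Counter()
    bases: Counter[tuple[int, int]] = Counter()
    for sig in signals:
        key = (sig.bp5, sig.bp3)
        votes[key] += 1
        bases[key] += sig.aligned_bases

    remaining = dict(votes)
    out: list[BreakpointCandidate] = []
    while remaining:
        winner = min(
            remaining,
            key=lambda k: (-remaining[k], -bases[k], k[0], k[1]),
        )
        total = 0
        for key in list(remaining):
            if abs(key[0] - winner[0]) <= cluster_tol and \
                    abs(key[1] - winner[1]) <= cluster_tol:
                total += remaining.pop(key)
        out.append(BreakpointCandidate(bp5=winner[0], bp3=winner[1], votes=total))
    return out


# ---------------------------------------------------------------------------
# Reconstruction and recalibration
# ---------------------------------------------------------------------------

def canonicalize_breakpoint(seq5: str, bp5: int, seq3: str,
                            bp3: int) -> tuple[int, int]:
    """Left-most representative of a breakpoint's equivalence class.

    When the bases flanking a junction agree between the two genes
    (junctional micro-homology), every breakpoint inside the homology run
    reconstructs the *identical* fusion sequence; split reads drift across
    the run depending on how their alignments extend.  Both the caller and
    any ground truth must therefore agree on one representative: the pair
    is shifted left while ``seq5[bp5-1] == seq3[bp3-1]`` holds.
    """
    while bp5 > 1 and bp3 > 0 and seq5[bp5 - 1] == seq3[bp3 - 1]:
        bp5 -= 1
        bp3 -= 1
    return bp5, bp3


def reconstruct_fusion(seq5: str, bp5: int, seq3: str, bp3: int) -> FusionRef:
    """Concatenate the 5' prefix and 3' suffix around the breakpoint.

    ``fusion_seq = seq5[:bp5] + seq3[bp3:]`` with the junction at ``bp5``.
    """
    if not 0 < bp5 <= len(seq5):
        raise ValueError(f"bp5={bp5} out of range (0, {len(seq5)}]")
    if not 0 <= bp3 < len(seq3):
        raise ValueError(f"bp3={bp3} out of range [0, {len(seq3)})")
    return FusionRef(seq=seq5[:bp5] + seq3[bp3:], junction_pos=bp5)


class RecalibrationResult(NamedTuple):
    support: int
    fragments: list[tuple[int, int]]
    supporting_ids: list[str]
    alignments: dict[str, ReadAlignment]


def recalibrate(candidate_reads: Iterable[tuple[str, str]], fusion_ref: FusionRef,
                params: ScoringParams = DEFAULT_SCORING, min_overlap: int = 5,
                template_of: Mapping[str, str] | None = None,
                seed_k: int | None = None) -> RecalibrationResult:
    """Re-align candidate reads to a reconstructed fusion and count support.

    ``candidate_reads`` yields ``(read_id, sequence)``.  A read supports the
    junction iff its matched reference interval covers
    ``[junction_pos - min_overlap, junction_pos + min_overlap)``; for every
    supporting read the (left, right) fragment lengths around the junction
    are recorded for the balance test.  When ``template_of`` maps read ids to
    template (pair) ids, a read pair counts once toward support, though each
    supporting mate still contributes a fragment pair.  The best alignment of
    every candidate is returned for the back-splice search.

    With ``seed_k`` set, reads are k-mer screened against the fusion
    sequence first and the exact DP runs only on the seeded strand(s) and
    reference window — the fast path used by the pipeline on large inputs.
    """
    jp = fusion_ref.junction_pos
    support_templates: set[str] = set()
    fragments: list[tuple[int, int]] = []
    supporting: list[str] = []
    alignments: dict[str, ReadAlignment] = {}
    for read_id, best in _best_fusion_alignments(candidate_reads, fusion_ref,
                                                 params, seed_k):
        best = trim_terminal_gap_blocks(best, ref=fusion_ref.seq)
        alignments[read_id] = best
        if best.ref_start <= jp - min_overlap and best.ref_end >= jp + min_overlap:
            supporting.append(read_id)
            fragments.append((jp - best.ref_start, best.ref_end - jp))
            support_templates.add(template_of.get(read_id, read_id)
                                  if template_of else read_id)
    return RecalibrationResult(
        support=len(support_templates),
        fragments=fragments,
        supporting_ids=supporting,
        alignments=alignments,
    )


def _best_fusion_alignments(candidate_reads: Iterable[tuple[str, str]],
                            fusion_ref: FusionRef, params: ScoringParams,
                            seed_k: int | None):
    """Yield (read_id, best alignment) per candidate read; exact DP either on
    the full fusion sequence (both strands) or on seeded windows."""
    if seed_k is None:
        for read_id, seq in candidate_reads:
            hits = local_align(seq, fusion_ref.seq, params, read_id=read_id)
            if hits:
                yield read_id, max(hits, key=lambda a: a.score)
        return
    from circfuse.seedindex import KmerIndex, seed_window

    reads = list(candidate_reads)
    index = KmerIndex({"F": fusion_ref.seq}, k=seed_k)
    scan = index.scan([seq for _, seq in reads])
    for i, (read_id, seq) in enumerate(reads):
        targets = scan.get(i)
        if not targets:
            continue
        best: ReadAlignment | None = None
        for (_, strand), bounds in sorted(targets.items()):
            lo, hi = seed_window(bounds, seed_k, len(seq), len(fusion_ref.seq))
            for aln in local_align(seq, fusion_ref.seq[lo:hi], params,
                                   read_id=read_id, strands=strand):
                aln.ref_start += lo
                if best is None or aln.score > best.score:
                    best = aln
        if best is not None:
            yield read_id, best


# ---------------------------------------------------------------------------
# Balance test
# ---------------------------------------------------------------------------

def balance_test(left: Sequence[float], right: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired fragment lengths.

    Zero differences are dropped; with no non-zero differences the test is
    uninformative and returns 1.0.  For n <= 25 the exact null distribution
    of the rank sum is computed by counting-polynomial convolution over the
    (midrank-doubled) ranks, which stays exact under ties; larger samples
    use the normal approximation with tie and continuity corrections.
    """
    if len(left) != len(right):
        raise ValueError("left and right must have equal length")
    d = np.asarray(right, dtype=float) - np.asarray(left, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(np.int64)  # doubled midranks are integers
    w2 = int(r2[d > 0].sum())
    total = int(r2.sum())
    if n <= 25:
        counts = np.zeros(total + 1, dtype=np.float64)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:total + 1 - r]
            counts += shifted
        denom = 2.0 ** n
        p_le = counts[: w2 + 1].sum() / denom
        p_ge = counts[w2:].sum() / denom
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    w = w2 / 2.0
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(r2, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts) / 2.0).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Reporting filters
# ---------------------------------------------------------------------------

def filter_calls(calls: Sequence[FusionCall],
                 gene_coords: Mapping[str, tuple[str, int, int]] | None = None,
                 min_support: int = 3, readthrough_dist: int = 100_000,
                 drop_readthrough: bool = False,
                 balance_alpha: float | None = None) -> list[FusionCall]:
    """Apply the reporting filters to fusion calls.

    Calls with fewer than ``min_support`` junction reads are dropped.  With
    genomic ``gene_coords`` (gene -> (chrom, start, end)) supplied, calls
    whose genes lie on one chromosome less than ``readthrough_dist`` apart
    are flagged as read-through and, in benchmark mode
    (``drop_readthrough``), removed; without coordinates the flag stays
    unknown and nothing is dropped on that criterion.  ``balance_alpha``
    optionally drops calls whose junction coverage is significantly skewed.
    The filter is idempotent.
    """
    out: list[FusionCall] = []
    for call in calls:
        if call.support < min_support:
            continue
        if balance_alpha is not None and call.balance_p <= balance_alpha:
            continue
        if gene_coords is not None and call.gene5 in gene_coords \
                and call.gene3 in gene_coords:
            chrom5, s5, e5 = gene_coords[call.gene5]
            chrom3, s3, e3 = gene_coords[call.gene3]
            if chrom5 == chrom3:
                gap = max(s5, s3) - min(e5, e3)
                call.readthrough = gap < readthrough_dist
            else:
                call.readthrough = False
            if drop_readthrough and call.readthrough:
                continue
        out.append(call)
    return out
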