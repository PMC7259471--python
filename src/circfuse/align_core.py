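"""Alignment data model and the low-penalty soft-clip local aligner.

The fusion-read search needs alignments that *prefer clipping over forcing a
chimeric read through one reference*: a read straddling a fusion junction
should align as ``40M60S`` on the 5' partner and ``40S60M`` on the 3' partner.
This is achieved with a local affine-gap aligner whose objective charges a
flat, low per-base penalty for soft-clipped read ends (clip max = min = 1, cf.
HISAT2's ``--sp 1,1``) and accepts alignments down to a linear minimum score
``score_min(L) = 0 - 0.8 * L`` (cf. ``--score-min L,0,-0.8``).

The DP is exact (no seeding heuristics inside :func:`local_align`; candidate
pre-filtering happens at the pipeline level) and is numba-compiled for speed.
Reference ends are free; read ends pay the clip cost; alignments start and end
with an aligned base pair.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement (N-preserving)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode bases to uint8 codes A,C,G,T -> 0..3; anything else -> 4 (N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# CIGAR
# ---------------------------------------------------------------------------

class CigarOp(str, enum.Enum):
    M = "M"
    S = "S"
    I = "I"
    D = "D"
    N = "N"


_CIGAR_RE = re.compile(r"(\d+)([MSIDN])")


class Cigar:
    """Ordered list of (operation, length) pairs, SAM-style.

    Supported operations: M (aligned), S (soft clip), I (insertion to the
    reference), D (deletion), N (skipped reference / splice gap).  S may only
    occur as the first and/or last element; all lengths are positive.
    """

    __slots__ = ("ops",)

    def __init__(self, ops: Iterable[tuple[str, int]] = ()):
        self.ops: list[tuple[str, int]] = [(str(o), int(n)) for o, n in ops]
        self._validate()

    def _validate(self) -> None:
        for idx, (op, n) in enumerate(self.ops):
            if op not in "MSIDN":
                raise ValueError(f"unknown CIGAR operation {op!r}")
            if n <= 0:
                raise ValueError(f"CIGAR length must be positive, got {n}{op}")
            if op == "S" and idx not in (0, len(self.ops) - 1):
                raise ValueError("soft clip S may appear only at CIGAR ends")

    def __bool__(self) -> bool:
        return bool(self.ops)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Cigar) and self.ops == other.ops

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.ops)

    def __repr__(self) -> str:
        return f"Cigar({str(self)!r})"

    def __str__(self) -> str:
        if not self.ops:
            return "*"
        return "".join(f"{n}{op}" for op, n in self.ops)

    @property
    def read_len(self) -> int:
        """Read bases accounted for (M + S + I)."""
        return sum(n for op, n in self.ops if op in "MSI")

    @property
    def ref_span(self) -> int:
        """Reference bases consumed (M + D + N)."""
        return sum(n for op, n in self.ops if op in "MDN")

    @property
    def lead_clip(self) -> int:
        return self.ops[0][1] if self.ops and self.ops[0][0] == "S" else 0

    @property
    def tail_clip(self) -> int:
        return self.ops[-1][1] if self.ops and self.ops[-1][0] == "S" else 0


def parse_cigar(text: str) -> Cigar:
    """Parse a SAM CIGAR string; ``"*"`` yields an empty CIGAR."""
    if text == "*":
        return Cigar()
    pos = 0
    ops: list[tuple[str, int]] = []
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"invalid CIGAR string {text!r}")
        ops.append((m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(text) or not ops:
        raise ValueError(f"invalid CIGAR string {text!r}")
    return Cigar(ops)


# ---------------------------------------------------------------------------
# Alignment record
# ---------------------------------------------------------------------------

class AlnStatus(enum.IntFlag):
    """Alignment status bits, SAM FLAG-compatible where applicable."""

    NONE = 0
    UNMAPPED = 0x4
    MATE_UNMAPPED = 0x8
    REVERSE = 0x10


@dataclass
class ReadAlignment:
    """One alignment of one read (or mate) against one reference sequence.

    Coordinates are 0-based half-open.  ``cigar`` and the query interval refer
    to the *oriented* sequence (the reverse complement of ``seq`` for
    minus-strand alignments), matching SAM conventions.
    """

    read_id: str
    mate: int | None = None  # 1, 2 or None for single-end
    ref_id: str | None = None
    ref_start: int = 0
    strand: str = "+"
    status: AlnStatus = AlnStatus.NONE
    cigar: Cigar = field(default_factory=Cigar)
    score: int = 0
    seq: str = ""
    qual: str = ""

    def __post_init__(self) -> None:
        if self.is_unmapped:
            if self.cigar:
                raise ValueError("unmapped record must have empty CIGAR")
        elif self.ref_start < 0:
            raise ValueError("ref_start must be >= 0")

    @property
    def is_unmapped(self) -> bool:
        return bool(self.status & AlnStatus.UNMAPPED)

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.cigar.ref_span

    @property
    def q_start(self) -> int:
        """First aligned base in the oriented read (= leading soft clip)."""
        return self.cigar.lead_clip

    @property
    def q_end(self) -> int:
        """One past the last aligned base in the oriented read."""
        return self.cigar.read_len - self.cigar.tail_clip

    @property
    def oriented_seq(self) -> str:
        return self.seq if self.strand == "+" else revcomp(self.seq)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringParams:
    """Low-penalty scoring used for fusion-read re-alignment.

    The clip cost is flat per base (max = min = 1) and alignments with total
    score below ``score_min(L) = score_min_intercept + score_min_slope * L``
    are discarded.  Match/mismatch/gap values follow common local-alignment
    defaults; the clip and minimum-score settings are the ones that matter
    for chiastic-clip detection.  N scores as a mismatch.
    """

    match: int = 2
    mismatch: int = -4
    gap_open: int = -5
    gap_extend: int = -3
    softclip_penalty_per_base: int = -1
    score_min_intercept: float = 0.0
    score_min_slope: float = -0.8


DEFAULT_SCORING = ScoringParams()


def score_min(read_length: int, params: ScoringParams = DEFAULT_SCORING) -> float:
    """Minimum acceptable alignment score for a read of the given length."""
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    return params.score_min_intercept + params.score_min_slope * read_length


# ---------------------------------------------------------------------------
# Soft-clip local aligner (exact DP, numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_softclip(q, r, match, mismatch, gap_open, gap_extend, clip):  # pragma: no cover
    """Affine-gap local DP with per-base read-end clip costs.

    Objective: max over all alignments (starting and ending with an aligned
    base pair) of  segment_score + clip * (clipped read bases).  Reference
    ends are free.  Returns (score, qs, qe, rs, re, ops, n_ops) where ops is
    the M/I/D operation list (0=M, 1=I, 2=D) of the aligned segment and the
    intervals are 0-based half-open on the oriented read / reference.
    Ties are broken toward the smallest read end, then reference end.
    """
    L = q.shape[0]
    R = r.shape[0]
    NEG = np.int64(-(10 ** 12))
    H = np.full((L + 1, R + 1), NEG, dtype=np.int64)
    E = np.full((L + 1, R + 1), NEG, dtype=np.int64)
    F = np.full((L + 1, R + 1), NEG, dtype=np.int64)
    PH = np.zeros((L + 1, R + 1), dtype=np.uint8)
    PE = np.zeros((L + 1, R + 1), dtype=np.uint8)
    PF = np.zeros((L + 1, R + 1), dtype=np.uint8)

    best = NEG
    best_i = 0
    best_j = 0
    for i in range(1, L + 1):
        qb = q[i - 1]
        start = clip * (i - 1)
        tail = clip * (L - i)
        for j in range(1, R + 1):
            # E: gap in read (deletion, consumes reference base j-1)
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 0
            else:
                E[i, j] = e_ext
                PE[i, j] = 1
            # F: gap in reference (insertion, consumes read base i-1)
            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 0
            else:
                F[i, j] = f_ext
                PF[i, j] = 1
            # H: read base i-1 aligned to ref base j-1
            if qb == r[j - 1] and qb < 4:
                s = match
            else:
                s = mismatch
            hv = H[i - 1, j - 1]
            ptr = 0
            if E[i - 1, j - 1] > hv:
                hv = E[i - 1, j - 1]
                ptr = 1
            if F[i - 1, j - 1] > hv:
                hv = F[i - 1, j - 1]
                ptr = 2
            if start >= hv:  # ties clip rather than extend (canonical boundary)
                hv = start
                ptr = 3
            H[i, j] = hv + s
            PH[i, j] = ptr
            total = H[i, j] + tail
            if total > best:
                best = total
                best_i = i
                best_j = j

    # Traceback from (best_i, best_j) in state H.
    max_ops = L + R + 2
    ops = np.zeros(max_ops, dtype=np.uint8)
    n_ops = 0
    i = best_i
    j = best_j
    state = 0  # 0=H, 1=E, 2=F
    qs = 0
    rs = 0
    while True:
        if state == 0:
            ops[n_ops] = 0  # M
            n_ops += 1
            ptr = PH[i, j]
            i -= 1
            j -= 1
            if ptr == 3:
                qs = i
                rs = j
                break
            state = ptr
        elif state == 1:
            ops[n_ops] = 2  # D
            n_ops += 1
            ptr = PE[i, j]
            j -= 1
            state = 0 if ptr == 0 else 1
        else:
            ops[n_ops] = 1  # I
            n_ops += 1
            ptr = PF[i, j]
            i -= 1
            state = 0 if ptr == 0 else 2

    ops[:n_ops] = ops[:n_ops][::-1].copy()
    return best, qs, best_i, rs, best_j, ops, n_ops


_OP_CHARS = "MID"


class _RawAlignment(NamedTuple):
    score: int
    q_start: int
    q_end: int
    ref_start: int
    ref_end: int
    cigar: Cigar


def _align_codes(q_codes: np.ndarray, r_codes: np.ndarray,
                 params: ScoringParams) -> _RawAlignment:
    """Run the DP kernel and package the result (oriented-read coords)."""
    score, qs, qe, rs, re_, ops, n_ops = _sw_softclip(
        q_codes, r_codes,
        params.match, params.mismatch, params.gap_open, params.gap_extend,
        params.softclip_penalty_per_base,
    )
    L = q_codes.shape[0]
    cig: list[tuple[str, int]] = []
    if qs > 0:
        cig.append(("S", qs))
    run_op = -1
    run_len = 0
    for k in range(n_ops):
        o = int(ops[k])
        if o == run_op:
            run_len += 1
        else:
            if run_len:
                cig.append((_OP_CHARS[run_op], run_len))
            run_op = o
            run_len = 1
    if run_len:
        cig.append((_OP_CHARS[run_op], run_len))
    if L - qe > 0:
        cig.append(("S", L - qe))
    return _RawAlignment(int(score), int(qs), int(qe), int(rs), int(re_), Cigar(cig))


def local_align(read: str, ref: str, params: ScoringParams = DEFAULT_SCORING,
                read_id: str = "", ref_id: str | None = None,
                mate: int | None = None, qual: str = "",
                strands: str = "+-") -> list[ReadAlignment]:
    """Best soft-clip local alignment of ``read`` per strand against ``ref``.

    Both the forward read and its reverse complement are aligned (restrict
    with ``strands``); each strand's best alignment is returned as a
    :class:`ReadAlignment` provided its score (clip penalties included)
    reaches ``score_min(len(read))``.  The returned CIGAR expresses the
    alignment as leading/trailing S around internal M/I/D, in oriented-read
    coordinates.
    """
    if not read or not ref:
        raise ValueError("read and ref must be non-empty")
    threshold = score_min(len(read), params)
    ref_codes = encode(ref)
    out: list[ReadAlignment] = []
    for strand in strands:
        oriented = read if strand == "+" else revcomp(read)
        raw = _align_codes(encode(oriented), ref_codes, params)
        if raw.score < threshold:
            continue
        status = AlnStatus.NONE if strand == "+" else AlnStatus.REVERSE
        out.append(ReadAlignment(
            read_id=read_id, mate=mate, ref_id=ref_id, ref_start=raw.ref_start,
            strand=strand, status=status, cigar=raw.cigar, score=raw.score,
            seq=read, qual=qual,
        ))
    return out


def trim_terminal_gap_blocks(aln: ReadAlignment, min_block: int = 12,
                             ref: str | None = None,
                             min_identity: float = 0.85) -> ReadAlignment:
    """Convert unreliable gap-separated terminal match blocks into soft clips.

    Under the low per-base clip cost, the exhaustive DP happily extends an
    alignment past a junction through a small indel followed by a partially
    matching block (e.g. ``81M1D11M`` instead of ``81M19S``), which corrupts
    the clip boundary that chiastic-signal detection relies on.  This trims,
    from both ends, any aligned block that is separated from the rest of the
    alignment by an indel and is either shorter than ``min_block`` or — when
    the reference sequence is supplied — below ``min_identity`` exact
    matches, merging block and indel into the adjacent soft clip.  The DP
    chains such blocks freely (each gap costs little against the cheap
    clip), so the threshold must exceed the length of a chance match block
    reachable through arbitrary gap offsets; contiguous (gap-free) segments
    are never touched, so genuine chimeric-read segments survive intact.
    The raw alignment score is left untouched.
    """
    ops = list(aln.cigar.ops)
    if not ops:
        return aln
    oriented = aln.oriented_seq if ref is not None else None

    def block_ok(op_idx: int, q0: int, r0: int) -> bool:
        n = ops[op_idx][1]
        if n < min_block:
            return False
        if oriented is None:
            return True
        matches = sum(oriented[q0 + i] == ref[r0 + i] for i in range(n)
                      if r0 + i < len(ref))
        return matches >= min_identity * n

    # op coordinates (query offset in oriented read, reference position)
    def coords() -> list[tuple[int, int]]:
        out = []
        q, r = 0, aln.ref_start
        for op, n in ops:
            out.append((q, r))
            if op in "MSI":
                q += n
            if op in "MDN":
                r += n
        return out

    changed = False
    while True:
        pos = coords()
        m_idx = [i for i, (op, _) in enumerate(ops) if op == "M"]
        if len(m_idx) < 2:
            break
        first, last = m_idx[0], m_idx[-1]
        if not block_ok(first, *pos[first]):
            # merge block + following gap into the leading clip
            cut = ops[:first + 2]
            q_cut = sum(n for op, n in cut if op in "MSI")
            r_cut = sum(n for op, n in cut if op in "MDN")
            ops = [("S", q_cut)] + ops[first + 2:]
            aln = ReadAlignment(read_id=aln.read_id, mate=aln.mate,
                                ref_id=aln.ref_id,
                                ref_start=aln.ref_start + r_cut,
                                strand=aln.strand, status=aln.status,
                                cigar=Cigar(ops), score=aln.score,
                                seq=aln.seq, qual=aln.qual)
            ops = list(aln.cigar.ops)
            changed = True
            continue
        if not block_ok(last, *pos[last]):
            cut = ops[last - 1:]
            q_cut = sum(n for op, n in cut if op in "MSI")
            ops = ops[:last - 1] + [("S", q_cut)]
            aln = ReadAlignment(read_id=aln.read_id, mate=aln.mate,
                                ref_id=aln.ref_id, ref_start=aln.ref_start,
                                strand=aln.strand, status=aln.status,
                                cigar=Cigar(ops), score=aln.score,
                                seq=aln.seq, qual=aln.qual)
            ops = list(aln.cigar.ops)
            changed = True
            continue
        break
    return _extend_exact(aln, ref) if ref is not None else aln


def _extend_exact(aln: ReadAlignment, ref: str) -> ReadAlignment:
    """Greedily extend both alignment ends over exact base matches.

    Trimming a spurious gap block can strip bases that the junk path had
    stolen from the true terminal match run (e.g. ``72M1I6M21S`` whose last
    true base sat inside the insertion); exact-match extension restores
    them.  Extension stops at the first mismatch, so it can only add
    unambiguous (homology-equivalent) bases.
    """
    ops = list(aln.cigar.ops)
    if not ops or all(op != "M" for op, _ in ops):
        return aln
    oriented = aln.oriented_seq
    read_len = aln.cigar.read_len
    q_end, ref_end = aln.q_end, aln.ref_end
    grow_r = 0
    while q_end + grow_r < read_len and ref_end + grow_r < len(ref) \
            and oriented[q_end + grow_r] == ref[ref_end + grow_r]:
        grow_r += 1
    q_start, ref_start = aln.q_start, aln.ref_start
    grow_l = 0
    while q_start - grow_l > 0 and ref_start - grow_l > 0 \
            and oriented[q_start - grow_l - 1] == ref[ref_start - grow_l - 1]:
        grow_l += 1
    if not grow_l and not grow_r:
        return aln
    if grow_l:
        i = 1 if ops[0][0] == "S" else 0
        if i == 1:
            lead = ops[0][1] - grow_l
            ops = ([("S", lead)] if lead > 0 else []) + ops[1:]
            i = 1 if lead > 0 else 0
        ops[i] = ("M", ops[i][1] + grow_l)
    if grow_r:
        i = len(ops) - 2 if ops[-1][0] == "S" else len(ops) - 1
        if ops[-1][0] == "S":
            tail = ops[-1][1] - grow_r
            ops = ops[:-1] + ([("S", tail)] if tail > 0 else [])
        ops[i] = ("M", ops[i][1] + grow_r)
    return ReadAlignment(
        read_id=aln.read_id, mate=aln.mate, ref_id=aln.ref_id,
        ref_start=aln.ref_start - grow_l, strand=aln.strand, status=aln.status,
        cigar=Cigar(ops), score=aln.score, seq=aln.seq, qual=aln.qual)


def trim_noisy_segment_ends(aln: ReadAlignment, ref: str, window: int = 12,
                            left: bool = False,
                            right: bool = False) -> ReadAlignment | None:
    """Cut a segment end back past any mismatch in its terminal window.

    A split-read segment facing a junction should end in perfect matches:
    chance agreement with the partner sequence extends it past the true
    boundary, and once such an extension contains a mismatch the resulting
    breakpoint is no longer sequence-equivalent to the true one, so no
    canonicalization can repair it.  Trimming every aligned base up to the
    last mismatch found within the terminal ``window`` leaves either a
    clean (pure-homology) extension — which breakpoint canonicalization
    handles — or rejects the segment (returns ``None``) when nothing
    reliable remains.  The raw score is not adjusted.
    """
    oriented = aln.oriented_seq
    pairs: list[tuple[int, int, bool]] = []  # (q, r, is_match)
    q, r = 0, aln.ref_start
    for op, n in aln.cigar.ops:
        if op == "M":
            for i in range(n):
                ok = r + i < len(ref) and oriented[q + i] == ref[r + i]
                pairs.append((q + i, r + i, ok))
        if op in "MSI":
            q += n
        if op in "MDN":
            r += n
    if not pairs:
        return None
    s_idx, e_idx = 0, len(pairs)
    if right:
        while s_idx < e_idx:
            mm = [i for i in range(max(s_idx, e_idx - window), e_idx)
                  if not pairs[i][2]]
            if not mm:
                break
            e_idx = mm[-1]
    if left:
        while s_idx < e_idx:
            mm = [i for i in range(s_idx, min(e_idx, s_idx + window))
                  if not pairs[i][2]]
            if not mm:
                break
            s_idx = mm[0] + 1
    if s_idx >= e_idx:
        return None
    if s_idx == 0 and e_idx == len(pairs):
        return aln
    sub = pairs[s_idx:e_idx]
    read_len = aln.cigar.read_len
    cig: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if cig and cig[-1][0] == op:
            cig[-1] = (op, cig[-1][1] + n)
        else:
            cig.append((op, n))

    push("S", sub[0][0])
    last_q = last_r = None
    for q, r, _ in sub:
        if last_q is not None:
            push("I", q - last_q - 1)
            push("D", r - last_r - 1)
        push("M", 1)
        last_q, last_r = q, r
    push("S", read_len - (sub[-1][0] + 1))
    return _extend_exact(ReadAlignment(
        read_id=aln.read_id, mate=aln.mate, ref_id=aln.ref_id,
        ref_start=sub[0][1], strand=aln.strand, status=aln.status,
        cigar=Cigar(cig), score=aln.score, seq=aln.seq, qual=aln.qual), ref)


# ---------------------------------------------------------------------------
# Step-1 unaligned-read selection
# ---------------------------------------------------------------------------

def select_unaligned(records: Iterable[ReadAlignment],
                     layout: str = "single") -> list[ReadAlignment]:
    """Select the reads that failed the first (transcriptome) alignment.

    Single-end: keep records with the unmapped bit set.  Paired-end: keep
    *both* mates of every pair in which at least one mate is unmapped, so
    that downstream paired selection still sees complete pairs; a pair with a
    missing mate triggers a warning and the orphan is kept if it qualifies.
    Input order is preserved and no record is duplicated.
    """
    if layout == "single":
        return [rec for rec in records if rec.is_unmapped]
    if layout != "paired":
        raise ValueError(f"layout must be 'single' or 'paired', got {layout!r}")

    records = list(records)
    mates_seen: dict[str, set[int]] = {}
    any_unmapped: dict[str, bool] = {}
    for rec in records:
        mates_seen.setdefault(rec.read_id, set()).add(rec.mate or 0)
        any_unmapped[rec.read_id] = any_unmapped.get(rec.read_id, False) or rec.is_unmapped
    for read_id, mates in mates_seen.items():
        if len(mates) < 2:
            logger.warning("paired-end read %s is missing a mate; orphan kept", read_id)
    emitted: set[tuple[str, int]] = set()
    out: list[ReadAlignment] = []
    for rec in records:
        key = (rec.read_id, rec.mate or 0)
        if any_unmapped[rec.read_id] and key not in emitted:
            emitted.add(key)
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Step-3 partial-hit selection
# ---------------------------------------------------------------------------

class CandidateSelection(NamedTuple):
    """Reads worth investigating for fusion evidence.

    ``pcc``: read ids with a clipped (partially aligned) segment on at least
    one gene — these can carry a chiastic split signal.  ``support``: read
    ids fully explained by a single gene — no junction to explain, but kept
    for the later recalibration support count.
    """

    pcc: set[str]
    support: set[str]


def select_partial_hits(alnU: Iterable[ReadAlignment],
                        alnV: Iterable[ReadAlignment],
                        layout: str = "single",
                        min_clip: int = 8,
                        mate_of: dict[str, str] | None = None) -> CandidateSelection:
    """Split mapped reads into chiastic-split candidates vs support-only reads.

    A read is a PCC candidate when some alignment to either gene set leaves a
    soft clip of at least ``min_clip`` bases unexplained; a read whose best
    alignments are (near-)full-length matches to a single gene has nothing to
    explain and is retained only for support counting.  For paired-end data
    ``mate_of`` may map read keys to their template id so that a pair with at
    least one mapped mate keeps both mates in play.
    """
    pcc: set[str] = set()
    mapped: set[str] = set()
    for rec in list(alnU) + list(alnV):
        if rec.is_unmapped or not rec.cigar:
            continue
        mapped.add(rec.read_id)
        if rec.cigar.lead_clip >= min_clip or rec.cigar.tail_clip >= min_clip:
            pcc.add(rec.read_id)
    if layout == "paired" and mate_of:
        templates = {mate_of[r] for r in mapped if r in mate_of}
        for read_id, tpl in mate_of.items():
            if tpl in templates:
                mapped.add(read_id)
    return CandidateSelection(pcc=pcc, support=mapped - pcc)
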