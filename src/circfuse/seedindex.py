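"""Vectorized k-mer seeding: which (read, reference, strand) pairs to align.

The exact soft-clip DP is quadratic, so the pipeline first screens every
read against the reference sets with exact k-mer seeds (default k = 14,
both strands) and only runs the DP on seeded pairs, restricted to a
reference window around the seed matches — the same seed-and-extend role
the multiseed stage of a general spliced aligner plays in the original
workflow.  With random-sequence references the chance that a background
read seeds is ~``n_ref_kmers * n_read_kmers / 4^k``, i.e. ~1% at k = 14
for a 100 nt read against tens of kilobases of reference.

A fusion segment shorter than k cannot seed; such reads contribute no
chiastic signal on that side, which the majority-vote breakpoint inference
absorbs (segments below the clip threshold would be rejected anyway).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

_LUT = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

#: read index -> {(reference name, strand): (min kmer ref pos, max kmer ref pos)}
ScanHits = dict[int, dict[tuple[str, str], tuple[int, int]]]


def _codes_matrix(seqs: Sequence[str], pad_to: int) -> np.ndarray:
    """(n, pad_to) base-code matrix; padding and non-ACGT bases code as 4."""
    n = len(seqs)
    mat = np.full((n, pad_to), 4, dtype=np.int64)
    for i, s in enumerate(seqs):
        mat[i, :len(s)] = _LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    return mat


def _kmer_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes per row; windows touching a non-ACGT base
    (or padding) get -1."""
    n, length = mat.shape
    if length < k:
        return np.full((n, 0), -1, dtype=np.int64)
    mask = (1 << (2 * k)) - 1
    code = np.zeros(n, dtype=np.int64)
    valid_run = np.zeros(n, dtype=np.int64)
    out = np.empty((n, length - k + 1), dtype=np.int64)
    for j in range(length):
        base = mat[:, j]
        ok = base < 4
        code = ((code << 2) | (base & 3)) & mask
        valid_run = np.where(ok, valid_run + 1, 0)
        if j >= k - 1:
            out[:, j - k + 1] = np.where(valid_run >= k, code, -1)
    return out


class KmerIndex:
    """Exact k-mer index over a set of named reference sequences."""

    def __init__(self, refs: dict[str, str], k: int = 14):
        self.k = k
        self.names = list(refs)
        kmers: list[np.ndarray] = []
        ref_ids: list[np.ndarray] = []
        positions: list[np.ndarray] = []
        for idx, name in enumerate(self.names):
            seq = refs[name]
            codes = _kmer_codes(_codes_matrix([seq], len(seq)), k)[0]
            pos = np.nonzero(codes >= 0)[0]
            kmers.append(codes[pos])
            positions.append(pos)
            ref_ids.append(np.full(pos.shape, idx, dtype=np.int64))
        allk = np.concatenate(kmers) if kmers else np.empty(0, dtype=np.int64)
        allr = np.concatenate(ref_ids) if ref_ids else np.empty(0, dtype=np.int64)
        allp = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
        order = np.argsort(allk, kind="stable")
        self._kmers = allk[order]
        self._ref_ids = allr[order]
        self._positions = allp[order]

    def scan(self, seqs: Sequence[str], chunk: int = 50_000) -> ScanHits:
        """Seed hits per read: reference, strand and seed position bounds.

        Both the forward sequence ('+') and its reverse complement ('-') are
        screened; the strand tells which orientation of the read shares a
        k-mer with the (forward) reference.  The position bounds delimit
        where on the reference the matching k-mers start, so callers can
        restrict the exact alignment to a window.
        """
        hits: ScanHits = {}
        if self._kmers.size == 0 or not seqs:
            return hits
        n_refs = max(len(self.names), 1)
        for lo in range(0, len(seqs), chunk):
            batch = list(seqs[lo:lo + chunk])
            pad = max(len(s) for s in batch)
            mat = _codes_matrix(batch, pad)
            for strand in "+-":
                m = mat if strand == "+" else (
                    np.where(mat[:, ::-1] < 4, 3 - mat[:, ::-1], 4))
                codes = _kmer_codes(m, self.k)
                if codes.size == 0:
                    continue
                flat = codes.ravel()
                pos = np.searchsorted(self._kmers, flat)
                ok = (flat >= 0) & (pos < self._kmers.size)
                ok[ok] = self._kmers[pos[ok]] == flat[ok]
                if not ok.any():
                    continue
                idx = np.nonzero(ok)[0]
                reads = idx // codes.shape[1] + lo
                left = np.searchsorted(self._kmers, flat[idx], side="left")
                right = np.searchsorted(self._kmers, flat[idx], side="right")
                counts = right - left
                total = int(counts.sum())
                grp_base = np.repeat(left, counts)
                starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
                slot = grp_base + (np.arange(total) - np.repeat(starts, counts))
                exp_reads = np.repeat(reads, counts)
                ref_ids = self._ref_ids[slot]
                ref_pos = self._positions[slot]
                key = exp_reads * n_refs + ref_ids
                uniq, inv = np.unique(key, return_inverse=True)
                mins = np.full(uniq.shape, np.iinfo(np.int64).max, dtype=np.int64)
                maxs = np.full(uniq.shape, -1, dtype=np.int64)
                np.minimum.at(mins, inv, ref_pos)
                np.maximum.at(maxs, inv, ref_pos)
                for u, mn, mx in zip(uniq, mins, maxs):
                    read_i = int(u // n_refs)
                    name = self.names[int(u % n_refs)]
                    hits.setdefault(read_i, {})[(name, strand)] = (int(mn), int(mx))
        return hits


def seed_window(bounds: tuple[int, int], k: int, read_len: int,
                ref_len: int, pad: int = 32) -> tuple[int, int]:
    """Reference window guaranteed to contain any alignment anchored on the
    seeds: seeds span ``[mn, mx + k)``; an extension beyond them is at most
    the read length."""
    mn, mx = bounds
    lo = max(0, mn - read_len - pad)
    hi = min(ref_len, mx + k + read_len + pad)
    return lo, hi
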