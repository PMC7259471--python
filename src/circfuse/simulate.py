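"""Seeded RNA-Seq read simulator for fusion transcripts and f-circRNAs.

The generator emulates the evaluation design used for fusion/circle callers:
random gene sequences stand in for real transcripts (the pipeline is
sequence-content-agnostic), fusion transcripts are built by joining an
upstream fragment to a downstream fragment at designed breakpoints, linear
fusion reads are drawn uniformly from the fusion sequence, circular reads
are drawn from the doubled circle sequence so that reads crossing the seam
carry the back-splice junction, and a non-fusion background fills the rest.
Linear fusion reads are emitted at 2.5 times the circular read count; the
condition grid covers coverages 20/50/100x and read lengths 50/100 nt in
single- or paired-end layout.

Every read name encodes its origin, and a :class:`TruthSet` records designed
breakpoints, circle intervals and per-origin read counts so that calls can
be benchmarked string-exactly.  Everything is deterministic for a seed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from circfuse.fusion_call import canonicalize_breakpoint, reconstruct_fusion

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
KMER_GUARD = 30  # background shares no 30-mer with any fusion sequence


class FusionDesign(NamedTuple):
    gene5: str
    gene3: str
    bp5: int
    bp3: int


class CircleDesign(NamedTuple):
    fusion: int  # index into fusion_designs
    circle_start: int  # 0-based, on the fusion sequence
    circle_end: int  # half-open


@dataclass(frozen=True)
class SimConfig:
    """Simulation design and sequencing conditions.

    ``linear_circ_ratio`` ties the linear fusion read count of a fusion to
    its circular read count (2.5 linear reads per circular read); fusions
    without a circle design get coverage-scaled linear reads instead.
    ``background_factor`` scales the non-fusion background relative to the
    total designed fusion read count.  Read counts are in read records
    (each mate of a pair counts one).
    """

    seed: int = 0
    layout: str = "paired"  # or "single"
    read_len: int = 100
    coverage: int = 100
    frag_mean: float = 250.0
    frag_sd: float = 30.0
    err_rate: float = 0.001
    linear_circ_ratio: float = 2.5
    n_background_transcripts: int = 20
    background_factor: float = 20.0
    gene_len_range: tuple[int, int] = (1000, 3000)
    fusion_designs: tuple[FusionDesign, ...] = ()
    circle_designs: tuple[CircleDesign, ...] = ()
    emit_circles: bool = True  # False: linear-only control, same designed counts


def default_design(**overrides) -> SimConfig:
    """The bundled evaluation design: 4 fusion gene pairs, 2 circles each.

    Eight f-circRNAs across EML4–ALK, EWSR1–FLI1, KMT2A–MLLT3 and PML–RARA,
    every circle spanning its fusion point, circle lengths 400–600 nt
    summing to 1000 per fusion so read counts divide evenly across the
    coverage/read-length grid.
    """
    fusions = (
        FusionDesign("EML4", "ALK", 1200, 800),
        FusionDesign("EWSR1", "FLI1", 900, 600),
        FusionDesign("KMT2A", "MLLT3", 1500, 400),
        FusionDesign("PML", "RARA", 1000, 700),
    )
    circles = (
        CircleDesign(0, 950, 1500),   # len 550
        CircleDesign(0, 1020, 1470),  # len 450
        CircleDesign(1, 650, 1250),   # len 600
        CircleDesign(1, 700, 1100),   # len 400
        CircleDesign(2, 1250, 1750),  # len 500
        CircleDesign(2, 1200, 1700),  # len 500
        CircleDesign(3, 760, 1290),   # len 530
        CircleDesign(3, 800, 1270),   # len 470
    )
    return SimConfig(fusion_designs=fusions, circle_designs=circles, **overrides)


def benchmark_design(n_fusions: int = 10, **overrides) -> SimConfig:
    """A linear-only benchmark design: ``n_fusions`` fusions, no circles.

    Gene pairs reuse recurrent cancer fusion symbols; breakpoints follow a
    fixed deterministic pattern so only the sequences vary with the seed.
    """
    symbols = [
        ("BCR", "ABL1"), ("ETV6", "RUNX1"), ("TMPRSS2", "ERG"),
        ("CD74", "ROS1"), ("CCDC6", "RET"), ("AKAP9", "BRAF"),
        ("BRD4", "NUTM1"), ("FGFR3", "TACC3"), ("DNAJB1", "PRKACA"),
        ("NPM1", "ALK"), ("EWSR1", "ATF1"), ("KMT2A", "AFF1"),
    ]
    if n_fusions > len(symbols):
        raise ValueError(f"at most {len(symbols)} benchmark fusions available")
    fusions = tuple(
        FusionDesign(g5, g3, 700 + (97 * i) % 600, 350 + (61 * i) % 400)
        for i, (g5, g3) in enumerate(symbols[:n_fusions])
    )
    overrides.setdefault("coverage", 50)
    return SimConfig(fusion_designs=fusions, **overrides)


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated dataset."""

    fusions: list[FusionDesign] = field(default_factory=list)
    circles: list[tuple[str, str, int, int]] = field(default_factory=list)
    origins: dict[str, str] = field(default_factory=dict)  # template id -> origin
    counts: Counter = field(default_factory=Counter)  # origin -> read records

    def origin_class(self, read_id: str) -> str:
        origin = self.origins[read_id.split("/")[0]]
        return origin.split(".")[0]


class SimRead(NamedTuple):
    seq1: str
    seq2: str | None  # None for single-end
    start: int
    frag_len: int


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def _random_codes(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _rows_to_strs(mat: np.ndarray) -> list[str]:
    n, length = mat.shape
    raw = _BASES[mat].tobytes()
    return [raw[i * length:(i + 1) * length].decode("ascii") for i in range(n)]


def _mutate(mat: np.ndarray, err_rate: float, rng: np.random.Generator) -> None:
    if err_rate <= 0:
        return
    mask = rng.random(mat.shape) < err_rate
    k = int(mask.sum())
    if k:
        mat[mask] = (mat[mask] + rng.integers(1, 4, size=k, dtype=np.uint8)) % 4


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------

@dataclass
class References:
    genes: dict[str, str]
    fusion_seqs: list[str]  # aligned with config.fusion_designs
    background: dict[str, str]


def make_references(config: SimConfig, rng: np.random.Generator) -> References:
    """Generate gene, fusion and background sequences for a design.

    Gene lengths are drawn from ``gene_len_range`` but always leave at least
    200 nt beyond any designed breakpoint (and enough 3' sequence for every
    designed circle).  Background transcripts are rejection-sampled until
    they share no 30-mer with any fusion sequence (either strand), so
    background reads cannot mimic fusion segments.
    """
    lo, hi = config.gene_len_range
    need: dict[str, int] = {}
    for i, fd in enumerate(config.fusion_designs):
        need[fd.gene5] = max(need.get(fd.gene5, 0), fd.bp5 + 200)
        tail = max((c.circle_end - fd.bp5 for c in config.circle_designs
                    if c.fusion == i), default=0)
        need[fd.gene3] = max(need.get(fd.gene3, 0), fd.bp3 + max(tail, 0) + 200)
    genes: dict[str, str] = {}
    for gene in sorted(need):
        length = max(int(rng.integers(lo, hi + 1)), need[gene])
        genes[gene] = _codes_to_str(_random_codes(length, rng))

    fusion_seqs = [
        reconstruct_fusion(genes[fd.gene5], fd.bp5, genes[fd.gene3], fd.bp3).seq
        for fd in config.fusion_designs
    ]

    forbidden: set[str] = set()
    from circfuse.align_core import revcomp

    for fs in fusion_seqs:
        forbidden |= _kmer_set(fs, KMER_GUARD)
        forbidden |= _kmer_set(revcomp(fs), KMER_GUARD)
    background: dict[str, str] = {}
    for i in range(config.n_background_transcripts):
        while True:
            length = int(rng.integers(lo, hi + 1))
            seq = _codes_to_str(_random_codes(length, rng))
            if not (_kmer_set(seq, KMER_GUARD) & forbidden):
                break
        background[f"bgt{i:03d}"] = seq
    return References(genes=genes, fusion_seqs=fusion_seqs, background=background)


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

def simulate_reads(seq: str, n_reads: int, read_len: int, layout: str = "single",
                   frag_mean: float = 250.0, frag_sd: float = 30.0,
                   err_rate: float = 0.0,
                   rng: np.random.Generator | None = None) -> list[SimRead]:
    """Sample reads uniformly from a linear sequence.

    Single-end reads take a random strand; paired-end fragments are FR
    (mate 1 forward, mate 2 the reverse complement of the fragment's other
    end).  Substitution errors hit each base independently with
    ``err_rate``.  ``n_reads`` counts read records; a pair contributes two,
    so ``ceil(n_reads / 2)`` fragments are drawn.
    """
    rng = rng if rng is not None else np.random.default_rng()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 0, dtype=np.uint8)
    for b, c in zip(b"ACGT", range(4)):
        lut[b] = c
    codes = lut[codes]
    slen = len(seq)
    if read_len > slen:
        raise ValueError(f"read_len {read_len} exceeds sequence length {slen}")
    out: list[SimRead] = []
    if layout == "single":
        if n_reads <= 0:
            return out
        starts = rng.integers(0, slen - read_len + 1, size=n_reads)
        mat = codes[starts[:, None] + np.arange(read_len)]
        flip = rng.random(n_reads) < 0.5
        mat[flip] = 3 - mat[flip][:, ::-1]
        _mutate(mat, err_rate, rng)
        for s, row in zip(starts, _rows_to_strs(mat)):
            out.append(SimRead(row, None, int(s), read_len))
        return out
    if layout != "paired":
        raise ValueError(f"unknown layout {layout!r}")
    if frag_mean > slen:
        raise ValueError(f"frag_mean {frag_mean} exceeds sequence length {slen}")
    n_pairs = math.ceil(n_reads / 2)
    if n_pairs <= 0:
        return out
    frags = np.clip(np.rint(rng.normal(frag_mean, frag_sd, size=n_pairs)),
                    read_len, slen).astype(np.int64)
    starts = (rng.random(n_pairs) * (slen - frags + 1)).astype(np.int64)
    m1 = codes[starts[:, None] + np.arange(read_len)]
    ends = starts + frags
    m2 = codes[(ends - read_len)[:, None] + np.arange(read_len)]
    m2 = 3 - m2[:, ::-1]  # mate 2 reverse-complemented
    _mutate(m1, err_rate, rng)
    _mutate(m2, err_rate, rng)
    for s, f, r1, r2 in zip(starts, frags, _rows_to_strs(m1), _rows_to_strs(m2)):
        out.append(SimRead(r1, r2, int(s), int(f)))
    return out


def simulate_circle_reads(fusion_seq: str, circle_start: int, circle_end: int,
                          n_reads: int, read_len: int, layout: str = "single",
                          frag_mean: float = 250.0, frag_sd: float = 30.0,
                          err_rate: float = 0.0,
                          rng: np.random.Generator | None = None) -> list[SimRead]:
    """Sample reads from a circle on the fusion sequence.

    The circle ``C = fusion_seq[circle_start:circle_end]`` is doubled and
    reads start uniformly in ``[0, len(C))``; a read (or fragment) whose
    span crosses ``len(C)`` wraps around the back-splice seam.  ``start`` in
    the returned records is the circle-relative rotation offset.
    """
    circ = fusion_seq[circle_start:circle_end]
    clen = len(circ)
    if layout == "single" and clen < read_len:
        raise ValueError(f"circle length {clen} shorter than read length {read_len}")
    if layout == "paired" and clen < frag_mean:
        raise ValueError(f"circle length {clen} shorter than frag_mean {frag_mean}")
    rng = rng if rng is not None else np.random.default_rng()
    doubled = circ + circ
    lut = np.full(256, 0, dtype=np.uint8)
    for b, c in zip(b"ACGT", range(4)):
        lut[b] = c
    codes = lut[np.frombuffer(doubled.encode("ascii"), dtype=np.uint8)]
    out: list[SimRead] = []
    if layout == "single":
        if n_reads <= 0:
            return out
        starts = rng.integers(0, clen, size=n_reads)
        mat = codes[starts[:, None] + np.arange(read_len)]
        flip = rng.random(n_reads) < 0.5
        mat[flip] = 3 - mat[flip][:, ::-1]
        _mutate(mat, err_rate, rng)
        for s, row in zip(starts, _rows_to_strs(mat)):
            out.append(SimRead(row, None, int(s), read_len))
        return out
    n_pairs = math.ceil(n_reads / 2)
    if n_pairs <= 0:
        return out
    frags = np.clip(np.rint(rng.normal(min(frag_mean, clen), frag_sd,
                                       size=n_pairs)),
                    read_len, clen).astype(np.int64)
    starts = rng.integers(0, clen, size=n_pairs)
    m1 = codes[starts[:, None] + np.arange(read_len)]
    ends = starts + frags
    m2 = codes[(ends - read_len)[:, None] + np.arange(read_len)]
    m2 = 3 - m2[:, ::-1]
    _mutate(m1, err_rate, rng)
    _mutate(m2, err_rate, rng)
    for s, f, r1, r2 in zip(starts, frags, _rows_to_strs(m1), _rows_to_strs(m2)):
        out.append(SimRead(r1, r2, int(s), int(f)))
    return out


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

class SimulatedDataset(NamedTuple):
    fastq1: Path
    fastq2: Path | None
    genes_fasta: Path
    background_fasta: Path
    pairs_tsv: Path
    truth: TruthSet
    references: References
    config: SimConfig


def _design_counts(config: SimConfig,
                   fusion_seqs: list[str]) -> tuple[list[int], list[list[int]]]:
    """Designed read-record counts: per-fusion linear, per-fusion circular."""
    n_lin: list[int] = []
    n_circ: list[list[int]] = []
    for i, fd in enumerate(config.fusion_designs):
        circ_counts = [
            math.ceil(config.coverage * (c.circle_end - c.circle_start)
                      / config.read_len)
            for c in config.circle_designs if c.fusion == i
        ]
        n_circ.append(circ_counts)
        if circ_counts:
            n_lin.append(round(config.linear_circ_ratio * sum(circ_counts)))
        else:
            n_lin.append(math.ceil(config.coverage * len(fusion_seqs[i])
                                   / config.read_len))
    return n_lin, n_circ


def build_dataset(config: SimConfig, out_dir: str | Path) -> SimulatedDataset:
    """Generate FASTQ reads, reference FASTA files and the truth set.

    Per fusion with circle designs, circular reads are coverage-scaled over
    each circle length and linear fusion reads are emitted at
    ``linear_circ_ratio`` times the circular count; fusions without circles
    get coverage-scaled linear reads.  Background reads are
    ``background_factor`` times the total designed fusion read count,
    spread over background transcripts proportionally to length.  With
    ``emit_circles=False`` circular reads are withheld while the linear and
    background counts keep their designed values (linear-only control).
    Output is byte-identical for identical config (incl. seed).
    """
    if not config.fusion_designs:
        raise ValueError("config needs at least one fusion design")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    refs = make_references(config, rng)
    n_lin, n_circ = _design_counts(config, refs.fusion_seqs)

    # Truth coordinates are stored in canonical (left-most equivalent) form:
    # with chance micro-homology at a junction, every breakpoint inside the
    # homology run yields the identical fusion sequence, so caller and truth
    # must agree on one representative.
    truth = TruthSet(fusions=[
        FusionDesign(fd.gene5, fd.gene3, *canonicalize_breakpoint(
            refs.genes[fd.gene5], fd.bp5, refs.genes[fd.gene3], fd.bp3))
        for fd in config.fusion_designs
    ])
    paired = config.layout == "paired"
    entries: list[tuple[str, str, str | None]] = []  # (template_id, seq1, seq2)

    def emit(origin: str, reads: list[SimRead]) -> None:
        for serial, rec in enumerate(reads):
            template = f"{origin}|{serial}"
            truth.origins[template] = origin
            truth.counts[origin] += 2 if rec.seq2 is not None else 1
            entries.append((template, rec.seq1, rec.seq2))

    circle_idx = {i: [c for c in config.circle_designs if c.fusion == i]
                  for i in range(len(config.fusion_designs))}
    for i, fd in enumerate(config.fusion_designs):
        fseq = refs.fusion_seqs[i]
        emit(f"linear_fusion.{i}", simulate_reads(
            fseq, n_lin[i], config.read_len, config.layout,
            config.frag_mean, config.frag_sd, config.err_rate, rng))
        for j, (circle, n) in enumerate(zip(circle_idx[i], n_circ[i])):
            cs, ce = circle.circle_start, circle.circle_end
            while cs > 0 and fseq[cs - 1] == fseq[ce - 1]:  # canonical rotation
                cs -= 1
                ce -= 1
            truth.circles.append((fd.gene5, fd.gene3, cs, ce))
            if not config.emit_circles:
                continue
            emit(f"circular.{i}.{j}", simulate_circle_reads(
                fseq, circle.circle_start, circle.circle_end, n,
                config.read_len, config.layout, config.frag_mean,
                config.frag_sd, config.err_rate, rng))

    total_fusion = sum(n_lin) + sum(sum(c) for c in n_circ)
    n_bg = round(config.background_factor * total_fusion)
    bg_names = list(refs.background)
    lengths = np.array([len(refs.background[n]) for n in bg_names], dtype=float)
    shares = np.floor(n_bg * lengths / lengths.sum()).astype(int)
    shares[0] += n_bg - int(shares.sum())
    for name, share in zip(bg_names, shares):
        if share > 0:
            emit(f"background.{name}", simulate_reads(
                refs.background[name], int(share), config.read_len,
                config.layout, min(config.frag_mean, len(refs.background[name])),
                config.frag_sd, config.err_rate, rng))

    order = rng.permutation(len(entries))

    qual = "?" * config.read_len  # constant Q30
    fq1 = out_dir / ("reads_1.fastq" if paired else "reads.fastq")
    fq2 = out_dir / "reads_2.fastq" if paired else None
    with open(fq1, "w") as f1:
        if paired:
            f2 = open(fq2, "w")
        try:
            for idx in order:
                template, s1, s2 = entries[idx]
                f1.write(f"@{template}\n{s1}\n+\n{qual}\n")
                if paired:
                    f2.write(f"@{template}\n{s2}\n+\n{qual}\n")
        finally:
            if paired:
                f2.close()

    genes_fa = out_dir / "genes.fa"
    with open(genes_fa, "w") as fh:
        for gene in sorted(refs.genes):
            fh.write(f">{gene}\n{refs.genes[gene]}\n")
    bg_fa = out_dir / "background.fa"
    with open(bg_fa, "w") as fh:
        for name in sorted(refs.background):
            fh.write(f">{name}\n{refs.background[name]}\n")
    pairs_tsv = out_dir / "pairs.tsv"
    with open(pairs_tsv, "w") as fh:
        fh.write("# gene5\tgene3\tsource\n")
        for fd in config.fusion_designs:
            fh.write(f"{fd.gene5}\t{fd.gene3}\tsimulated\n")

    _write_truth(out_dir, config, truth)
    return SimulatedDataset(fastq1=fq1, fastq2=fq2, genes_fasta=genes_fa,
                            background_fasta=bg_fa, pairs_tsv=pairs_tsv,
                            truth=truth, references=refs, config=config)


def _write_truth(out_dir: Path, config: SimConfig, truth: TruthSet) -> None:
    with open(out_dir / "truth_fusions.tsv", "w") as fh:
        fh.write("gene5\tgene3\tbp5\tbp3\n")
        for fd in truth.fusions:
            fh.write(f"{fd.gene5}\t{fd.gene3}\t{fd.bp5}\t{fd.bp3}\n")
    with open(out_dir / "truth_circles.tsv", "w") as fh:
        fh.write("gene5\tgene3\tcircle_start\tcircle_end\n")
        for g5, g3, s, e in truth.circles:
            fh.write(f"{g5}\t{g3}\t{s}\t{e}\n")
    with open(out_dir / "read_origins.tsv", "w") as fh:
        fh.write("read_id\torigin\n")
        for template, origin in truth.origins.items():
            fh.write(f"{template}\t{origin}\n")


def control_config(config: SimConfig) -> SimConfig:
    """Linear-only control: same design and counts, no circular reads emitted."""
    return replace(config, emit_circles=False)
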