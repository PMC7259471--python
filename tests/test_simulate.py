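"""Synthetic-data generator: references, read sampling, dataset assembly."""

import math

import numpy as np
import pytest

from circfuse.align_core import revcomp
from circfuse.io_utils import read_fastq
from circfuse.simulate import (
    KMER_GUARD,
    CircleDesign,
    FusionDesign,
    SimConfig,
    benchmark_design,
    build_dataset,
    control_config,
    default_design,
    make_references,
    simulate_circle_reads,
    simulate_reads,
)


def small_design(**overrides):
    overrides.setdefault("coverage", 20)
    overrides.setdefault("n_background_transcripts", 5)
    overrides.setdefault("background_factor", 2.0)
    return SimConfig(
        fusion_designs=(FusionDesign("EML4", "ALK", 1200, 800),
                        FusionDesign("PML", "RARA", 1000, 700)),
        circle_designs=(CircleDesign(0, 950, 1500),),
        **overrides)


class TestMakeReferences:
    def test_deterministic_for_seed(self):
        cfg = small_design()
        a = make_references(cfg, np.random.default_rng(7))
        b = make_references(cfg, np.random.default_rng(7))
        assert a.genes == b.genes
        assert a.background == b.background
        assert a.fusion_seqs == b.fusion_seqs

    def test_fusion_length_law(self, rng):
        cfg = small_design()
        refs = make_references(cfg, rng)
        for fd, fseq in zip(cfg.fusion_designs, refs.fusion_seqs):
            assert len(fseq) == fd.bp5 + len(refs.genes[fd.gene3]) - fd.bp3

    def test_background_shares_no_guard_kmer_with_fusions(self, rng):
        refs = make_references(small_design(), rng)
        fusion_kmers = set()
        for fseq in refs.fusion_seqs:
            for strand in (fseq, revcomp(fseq)):
                fusion_kmers.update(strand[i:i + KMER_GUARD]
                                    for i in range(len(strand) - KMER_GUARD + 1))
        for bseq in refs.background.values():
            bg_kmers = {bseq[i:i + KMER_GUARD]
                        for i in range(len(bseq) - KMER_GUARD + 1)}
            assert not (bg_kmers & fusion_kmers)

    def test_gene_lengths_leave_breakpoint_margin(self, rng):
        cfg = small_design()
        refs = make_references(cfg, rng)
        for fd in cfg.fusion_designs:
            assert len(refs.genes[fd.gene5]) >= fd.bp5 + 200
            assert len(refs.genes[fd.gene3]) >= fd.bp3 + 200


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        reads = simulate_reads(seq, 200, 50, "single", err_rate=0.0, rng=rng)
        assert len(reads) == 200
        for rec in reads:
            assert rec.seq1 in seq or revcomp(rec.seq1) in seq

    def test_paired_mates_bracket_the_fragment(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        reads = simulate_reads(seq, 100, 60, "paired", frag_mean=200,
                               frag_sd=10, err_rate=0.0, rng=rng)
        assert len(reads) == 50  # 100 records = 50 pairs
        for rec in reads:
            frag = seq[rec.start:rec.start + rec.frag_len]
            assert rec.seq1 == frag[:60]
            assert rec.seq2 == revcomp(frag[-60:])

    def test_read_longer_than_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_reads("ACGTACGT", 5, 50, "single", rng=rng)

    def test_substitution_rate_calibrated(self, rng):
        seq = "A" * 1000
        reads = simulate_reads(seq, 2000, 50, "single", err_rate=0.5, rng=rng)
        bases = "".join(r.seq1 for r in reads)  # 1e5 bases
        # strand flips preserve A<->T complement; errors leave A/T with
        # probability err/3 each, so non-(A|T) fraction estimates 2*err/3
        frac = sum(b in "CG" for b in bases) / len(bases)
        se = math.sqrt(0.5 * 2 / 3 * (1 - 1 / 3) / len(bases))
        assert abs(frac - 0.5 * 2 / 3) < 3 * se


class TestSimulateCircleReads:
    def test_reads_wrap_around_the_seam(self, rng):
        fusion = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        circ = fusion[100:250]
        doubled = circ + circ
        reads = simulate_circle_reads(fusion, 100, 250, 500, 40, "single",
                                      err_rate=0.0, rng=rng)
        for rec in reads:
            assert rec.seq1 in doubled or revcomp(rec.seq1) in doubled
            assert 0 <= rec.start < len(circ)

    def test_junction_crossing_fraction(self, rng):
        fusion = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        clen, rlen, n = 150, 40, 6000
        reads = simulate_circle_reads(fusion, 100, 250, n, rlen, "single",
                                      err_rate=0.0, rng=rng)
        crossing = sum(r.start > clen - rlen for r in reads)
        expected = (rlen - 1) / clen
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(crossing / n - expected) < 4 * se

    def test_circle_shorter_than_read_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_circle_reads("A" * 100, 10, 30, 5, 50, "single", rng=rng)


class TestBuildDataset:
    def test_linear_circular_ratio(self, tmp_path):
        cfg = default_design(seed=3, coverage=20, read_len=100, layout="paired")
        ds = build_dataset(cfg, tmp_path / "sim")
        lin = sum(n for o, n in ds.truth.counts.items()
                  if o.startswith("linear_fusion"))
        circ = sum(n for o, n in ds.truth.counts.items()
                   if o.startswith("circular"))
        assert circ > 0
        assert lin / circ == pytest.approx(2.5)

    def test_byte_identical_for_same_seed(self, tmp_path):
        cfg = small_design(seed=9)
        a = build_dataset(cfg, tmp_path / "a")
        b = build_dataset(cfg, tmp_path / "b")
        assert a.fastq1.read_bytes() == b.fastq1.read_bytes()
        if a.fastq2:
            assert a.fastq2.read_bytes() == b.fastq2.read_bytes()
        assert a.genes_fasta.read_bytes() == b.genes_fasta.read_bytes()

    def test_truth_counts_reconcile_with_fastq(self, tmp_path):
        cfg = small_design(seed=4, layout="paired")
        ds = build_dataset(cfg, tmp_path / "sim")
        per_origin = {}
        for path in (ds.fastq1, ds.fastq2):
            for rec in read_fastq(path):
                origin = ds.truth.origins[rec.read_id]
                per_origin[origin] = per_origin.get(origin, 0) + 1
        assert per_origin == dict(ds.truth.counts)

    def test_control_withholds_circular_reads_only(self, tmp_path):
        cfg = small_design(seed=5)
        full = build_dataset(cfg, tmp_path / "full")
        ctrl = build_dataset(control_config(cfg), tmp_path / "ctrl")
        assert not any(o.startswith("circular") for o in ctrl.truth.counts)
        for origin, n in full.truth.counts.items():
            if not origin.startswith("circular"):
                assert ctrl.truth.counts[origin] == n

    def test_truth_breakpoints_are_canonical(self, tmp_path):
        cfg = default_design(seed=6)
        ds = build_dataset(cfg, tmp_path / "sim")
        for fd in ds.truth.fusions:
            s5 = ds.references.genes[fd.gene5]
            s3 = ds.references.genes[fd.gene3]
            assert not (fd.bp5 > 1 and fd.bp3 > 0
                        and s5[fd.bp5 - 1] == s3[fd.bp3 - 1])

    def test_coverage_arithmetic(self, tmp_path):
        # a 550-base circle at 20x with 100-base reads yields 110 records
        cfg = small_design(seed=7, layout="single")
        ds = build_dataset(cfg, tmp_path / "sim")
        assert ds.truth.counts["circular.0.0"] == math.ceil(20 * 550 / 100)
        assert ds.truth.counts["linear_fusion.0"] == round(2.5 * 110)

    def test_benchmark_design_is_linear_only(self, tmp_path):
        cfg = benchmark_design(4, seed=1, coverage=20)
        assert not cfg.circle_designs
        ds = build_dataset(cfg, tmp_path / "sim")
        assert len(ds.truth.fusions) == 4
        assert not any(o.startswith("circular") for o in ds.truth.counts)
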