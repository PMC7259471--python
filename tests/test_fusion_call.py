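"""PCC signal detection, breakpoint inference and the balance test."""

import numpy as np
import pytest
from scipy import stats

from circfuse.align_core import ReadAlignment, ScoringParams, local_align, parse_cigar
from circfuse.fusion_call import (
    FusionCall,
    balance_test,
    canonicalize_breakpoint,
    detect_pcc,
    filter_calls,
    infer_breakpoints,
    PccSignal,
    reconstruct_fusion,
    recalibrate,
)
from helpers import random_seq, wilcoxon_exact_enum

PARAMS = ScoringParams()

# fixed toy partner genes; the read joins U[2:10] to V[5:17]
TOY_U = "GTTGTTTACGCCGTGAGTAGCTACTCATTTTCGTGTGACG"
TOY_V = "CGCTAGAAGCCCTGCTTCAAAGGGTTGGACTTACCGACCA"


def make_aln(read_id, gene, cigar, ref_start, strand="+", mate=None):
    c = parse_cigar(cigar)
    return ReadAlignment(read_id=read_id, mate=mate, ref_id=gene,
                         ref_start=ref_start, strand=strand, cigar=c,
                         seq="A" * c.read_len)


class TestDetectPcc:
    def test_complementary_clip_pattern(self):
        """The canonical chiastic pattern: 40M60S on the 5' gene and 40S60M
        on the 3' gene, same strand, splits the read at offset 40."""
        aln5 = make_aln("r", "EML4", "40M60S", 1060)
        aln3 = make_aln("r", "ALK", "40S60M", 800)
        sig = detect_pcc(aln5, aln3, min_clip=8, slack=3)
        assert sig is not None
        assert (sig.gene5, sig.gene3) == ("EML4", "ALK")
        assert sig.split_offset == 40
        assert (sig.bp5, sig.bp3) == (1100, 800)

    def test_argument_order_irrelevant(self):
        aln5 = make_aln("r", "EML4", "40M60S", 1060)
        aln3 = make_aln("r", "ALK", "40S60M", 800)
        assert detect_pcc(aln3, aln5) == detect_pcc(aln5, aln3)

    def test_full_match_is_not_chiastic(self):
        full = make_aln("r", "EML4", "100M", 0)
        other = make_aln("r", "ALK", "100M", 50)
        assert detect_pcc(full, other) is None

    def test_opposite_strands_rejected(self):
        aln5 = make_aln("r", "EML4", "40M60S", 1060, strand="+")
        aln3 = make_aln("r", "ALK", "40S60M", 800, strand="-")
        assert detect_pcc(aln5, aln3) is None

    def test_different_reads_is_usage_error(self):
        with pytest.raises(ValueError):
            detect_pcc(make_aln("a", "EML4", "40M60S", 0),
                       make_aln("b", "ALK", "40S60M", 0))

    def test_boundary_gap_beyond_slack_rejected(self):
        aln5 = make_aln("r", "EML4", "40M60S", 1060)
        aln3 = make_aln("r", "ALK", "48S52M", 800)  # 8-base unexplained gap
        assert detect_pcc(aln5, aln3, slack=3) is None

    def test_short_segment_rejected(self):
        aln5 = make_aln("r", "EML4", "5M95S", 100)
        aln3 = make_aln("r", "ALK", "5S95M", 800)
        assert detect_pcc(aln5, aln3, min_clip=8) is None

    def test_constructed_junction_read(self):
        """A read joining TOY_U[2:10] to TOY_V[5:17] yields bp5=10, bp3=5
        and split offset 8; segment placements confirmed by the aligner."""
        read = TOY_U[2:10] + TOY_V[5:17]
        (aln_u,) = local_align(read, TOY_U, PARAMS, read_id="r", ref_id="U",
                               strands="+")
        (aln_v,) = local_align(read, TOY_V, PARAMS, read_id="r", ref_id="V",
                               strands="+")
        assert str(aln_u.cigar) == "8M12S" and aln_u.ref_start == 2
        assert str(aln_v.cigar) == "8S12M" and aln_v.ref_start == 5
        sig = detect_pcc(aln_u, aln_v, min_clip=8, slack=3)
        assert (sig.gene5, sig.gene3, sig.bp5, sig.bp3, sig.split_offset) == \
            ("U", "V", 10, 5, 8)


class TestInferBreakpoints:
    def sig(self, bp5, bp3, aligned=100):
        return PccSignal(read_id="r", gene5="A", gene3="B", bp5=bp5, bp3=bp3,
                         split_offset=50, aligned_bases=aligned)

    def test_strict_majority(self):
        signals = [self.sig(10, 5)] * 4 + [self.sig(19, 16)]
        cands = infer_breakpoints(signals)
        assert (cands[0].bp5, cands[0].bp3, cands[0].votes) == (10, 5, 4)

    def test_singleton(self):
        (cand,) = infer_breakpoints([self.sig(10, 5)])
        assert (cand.bp5, cand.bp3, cand.votes) == (10, 5, 1)

    def test_tie_broken_by_aligned_bases(self):
        signals = [self.sig(10, 5, aligned=90)] * 2 + \
                  [self.sig(22, 17, aligned=60)] * 2
        cands = infer_breakpoints(signals)
        assert (cands[0].bp5, cands[0].bp3) == (10, 5)

    def test_jittered_votes_absorbed_into_winner(self):
        signals = [self.sig(10, 5)] * 4 + [self.sig(11, 6)] * 2
        cands = infer_breakpoints(signals, cluster_tol=2)
        assert len(cands) == 1
        assert (cands[0].bp5, cands[0].bp3, cands[0].votes) == (10, 5, 6)

    def test_distant_secondary_reported(self):
        signals = [self.sig(10, 5)] * 4 + [self.sig(200, 100)] * 2
        cands = infer_breakpoints(signals)
        assert [(c.bp5, c.bp3, c.votes) for c in cands] == \
            [(10, 5, 4), (200, 100, 2)]

    def test_empty_is_usage_error(self):
        with pytest.raises(ValueError):
            infer_breakpoints([])


class TestReconstructFusion:
    def test_worked_example(self):
        ref = reconstruct_fusion("ACGTACGTACGTACGTACGT", 10,
                                 "GGATCCGGATCCGGATCCGG", 5)
        assert ref.seq == "ACGTACGTAC" + "CGGATCCGGATCCGG"
        assert len(ref.seq) == 25
        assert ref.junction_pos == 10

    def test_full_concatenation_boundary(self):
        ref = reconstruct_fusion("AAAA", 4, "CCCC", 0)
        assert ref.seq == "AAAACCCC"

    @pytest.mark.parametrize("bp5,bp3", [(0, 1), (21, 1), (10, 20), (10, -1)])
    def test_out_of_range_rejected(self, bp5, bp3):
        with pytest.raises(ValueError):
            reconstruct_fusion("A" * 20, bp5, "C" * 20, bp3)

    @pytest.mark.parametrize("bp5,bp3", [(1, 0), (7, 3), (20, 19)])
    def test_length_law(self, rng, bp5, bp3):
        s5, s3 = random_seq(rng, 20), random_seq(rng, 20)
        ref = reconstruct_fusion(s5, bp5, s3, bp3)
        assert len(ref.seq) == bp5 + len(s3) - bp3

    def test_canonicalize_shifts_over_homology(self):
        # seq5[9] == seq3[4], so (10, 5) and (9, 4) reconstruct identically
        s5 = "AAAAAAAAGC"
        s3 = "TTTTC" + "GGGGG"
        assert s5[9] == s3[4]
        assert canonicalize_breakpoint(s5, 10, s3, 5) == (9, 4)
        a = reconstruct_fusion(s5, 10, s3, 5).seq
        b = reconstruct_fusion(s5, 9, s3, 4).seq
        assert a == b


class TestRecalibrate:
    @pytest.fixture
    def fusion_ref(self, rng):
        s5, s3 = random_seq(rng, 40), random_seq(rng, 40)
        return reconstruct_fusion(s5, 10, s3, 5)

    def test_junction_spanning_read_supports(self, fusion_ref):
        read = fusion_ref.seq[4:22]
        res = recalibrate([("r1", read)], fusion_ref, PARAMS, min_overlap=5)
        assert res.support == 1
        assert res.fragments == [(6, 12)]

    def test_read_short_of_junction_window_does_not_support(self, fusion_ref):
        res = recalibrate([("r1", fusion_ref.seq[0:9])], fusion_ref, PARAMS,
                          min_overlap=5)
        assert res.support == 0

    def test_no_candidates(self, fusion_ref):
        res = recalibrate([], fusion_ref, PARAMS)
        assert res.support == 0 and res.fragments == []

    def test_pair_counts_once(self, fusion_ref):
        reads = [("t/1", fusion_ref.seq[2:20]), ("t/2", fusion_ref.seq[4:22])]
        res = recalibrate(reads, fusion_ref, PARAMS, min_overlap=5,
                          template_of={"t/1": "t", "t/2": "t"})
        assert res.support == 1
        assert len(res.fragments) == 2

    def test_seeded_path_matches_full_path(self, fusion_ref):
        reads = [(f"r{i}", fusion_ref.seq[i:i + 20]) for i in range(0, 26, 5)]
        full = recalibrate(reads, fusion_ref, PARAMS)
        seeded = recalibrate(reads, fusion_ref, PARAMS, seed_k=8)
        assert seeded.support == full.support
        assert seeded.fragments == full.fragments


class TestBalanceTest:
    def test_all_zero_differences(self):
        assert balance_test([10, 12, 11], [10, 12, 11]) == 1.0

    def test_one_sided_shift_exact(self):
        # all five differences positive: p = 2 * (1/32) = 0.0625
        assert balance_test([5, 6, 7, 8, 9],
                            [15, 16, 14, 13, 17]) == pytest.approx(0.0625)

    def test_single_nonzero_difference(self):
        assert balance_test([3], [10]) == 1.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            balance_test([1, 2], [1])

    @pytest.mark.parametrize("case", range(30))
    def test_exact_null_matches_sign_enumeration(self, case):
        """Exact p-values (ties included) equal brute-force enumeration of
        every sign assignment, for n <= 10."""
        rng = np.random.default_rng(200 + case)
        n = int(rng.integers(1, 11))
        left = rng.integers(0, 8, n).astype(float)
        right = rng.integers(0, 8, n).astype(float)
        assert balance_test(left, right) == pytest.approx(
            wilcoxon_exact_enum(left, right))

    @pytest.mark.parametrize("case", range(10))
    def test_matches_scipy_on_tie_free_samples(self, case):
        rng = np.random.default_rng(300 + case)
        n = int(rng.integers(6, 16))
        d = np.unique(rng.integers(1, 1000, n * 2))[:n]
        signs = rng.choice([-1.0, 1.0], size=d.size)
        left = np.zeros(d.size)
        right = d * signs
        expected = stats.wilcoxon(right - left, method="exact",
                                  alternative="two-sided").pvalue
        assert balance_test(left, right) == pytest.approx(expected)

    def test_large_sample_normal_branch(self, rng):
        left = rng.integers(0, 50, 60).astype(float)
        right = left + rng.integers(-3, 4, 60)
        p = balance_test(left, right)
        assert 0.0 < p <= 1.0


class TestFilterCalls:
    def call(self, support=3, gene5="A", gene3="B", balance_p=0.5):
        return FusionCall(gene5=gene5, gene3=gene3, bp5=10, bp3=5,
                          fusion_seq="ACGT", junction_pos=10, support=support,
                          balance_p=balance_p)

    def test_support_threshold(self):
        calls = [self.call(support=3), self.call(support=2)]
        assert filter_calls(calls) == [calls[0]]

    def test_readthrough_flagged_and_dropped_in_benchmark_mode(self):
        coords = {"A": ("chr2", 1_000_000, 1_050_000),
                  "B": ("chr2", 1_080_000, 1_120_000)}
        call = self.call()
        kept = filter_calls([call], gene_coords=coords)
        assert kept and kept[0].readthrough is True
        assert filter_calls([self.call()], gene_coords=coords,
                            drop_readthrough=True) == []

    def test_different_chromosomes_kept(self):
        coords = {"A": ("chr2", 0, 1000), "B": ("chr5", 0, 1000)}
        (kept,) = filter_calls([self.call()], gene_coords=coords,
                               drop_readthrough=True)
        assert kept.readthrough is False

    def test_without_coords_readthrough_unknown(self):
        (kept,) = filter_calls([self.call()])
        assert kept.readthrough is None

    def test_balance_alpha_optional_filter(self):
        calls = [self.call(balance_p=0.01), self.call(balance_p=0.5)]
        assert filter_calls(calls, balance_alpha=0.05) == [calls[1]]

    def test_idempotent(self):
        calls = [self.call(support=s) for s in (1, 2, 3, 4)]
        once = filter_calls(calls)
        assert filter_calls(once) == once
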