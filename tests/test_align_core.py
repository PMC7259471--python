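"""CIGAR semantics, unaligned-read selection and the soft-clip aligner."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circfuse.align_core import (
    AlnStatus,
    Cigar,
    ReadAlignment,
    ScoringParams,
    local_align,
    parse_cigar,
    revcomp,
    score_min,
    select_partial_hits,
    select_unaligned,
    trim_terminal_gap_blocks,
)
from helpers import random_seq, sw_softclip_oracle

PARAMS = ScoringParams()


class TestCigar:
    @pytest.mark.parametrize("text,ops,read_len", [
        ("40S60M", [("S", 40), ("M", 60)], 100),
        ("10M2I5M", [("M", 10), ("I", 2), ("M", 5)], 17),
        ("5S10M3D5M2S", [("S", 5), ("M", 10), ("D", 3), ("M", 5), ("S", 2)], 22),
    ])
    def test_parse(self, text, ops, read_len):
        cigar = parse_cigar(text)
        assert cigar.ops == ops
        assert cigar.read_len == read_len

    def test_star_is_empty(self):
        assert not parse_cigar("*")

    @pytest.mark.parametrize("bad", ["", "10", "M10", "0M", "10X", "5M3S2M"])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_cigar(bad)

    @given(st.lists(
        st.tuples(st.sampled_from("MID"), st.integers(1, 99)), min_size=1,
        max_size=6))
    def test_roundtrip(self, core):
        # build a valid CIGAR: optional clips around a core starting/ending M
        ops = [("M", 5)] + core + [("M", 5)]
        text = "".join(f"{n}{op}" for op, n in ops)
        assert str(parse_cigar(text)) == text

    def test_ref_span_and_clips(self):
        cigar = parse_cigar("5S10M3D5M2S")
        assert cigar.ref_span == 18
        assert (cigar.lead_clip, cigar.tail_clip) == (5, 2)


class TestScoreMin:
    def test_linear_form(self):
        assert score_min(100, PARAMS) == -80.0
        assert score_min(50, PARAMS) == -40.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            score_min(0, PARAMS)


class TestLocalAlign:
    def test_identity(self, compiled_aligner):
        seq = "ACGTACGTACGTACGTACGT"
        (aln,) = local_align(seq, seq, PARAMS, strands="+")
        assert str(aln.cigar) == "20M"
        assert aln.score == 40
        assert (aln.ref_start, aln.ref_end) == (0, 20)

    def test_partial_prefix_is_clipped(self, rng):
        ref = random_seq(rng, 60)
        read = ref[2:10] + "T" * 12
        (aln,) = local_align(read, ref, PARAMS, strands="+")
        assert str(aln.cigar) == "8M12S"
        assert aln.ref_start == 2
        assert aln.score == 2 * 8 - 12

    def test_unrelated_read_discarded_by_threshold(self, rng):
        ref = random_seq(rng, 1000)
        for _ in range(5):
            read = random_seq(rng, 20)
            for aln in local_align(read, ref, PARAMS):
                assert aln.score >= score_min(20, PARAMS)
                oracle = sw_softclip_oracle(aln.oriented_seq, ref, PARAMS)
                assert aln.score == oracle

    @pytest.mark.parametrize("case", range(40))
    def test_agrees_with_exhaustive_dp_oracle(self, case, compiled_aligner):
        """Best score identical to an independently written full DP."""
        rng = np.random.default_rng(1000 + case)
        read = random_seq(rng, int(rng.integers(5, 31)))
        ref = random_seq(rng, int(rng.integers(20, 121)))
        oracle = sw_softclip_oracle(read, ref, PARAMS)
        hits = local_align(read, ref, PARAMS, strands="+")
        if oracle >= score_min(len(read), PARAMS):
            assert hits and hits[0].score == oracle
        else:
            assert not hits

    def test_reverse_complement_symmetry(self, rng):
        ref = random_seq(rng, 300)
        read = ref[100:160]
        fwd = {a.strand: a for a in local_align(read, ref, PARAMS)}
        rev = {a.strand: a for a in local_align(revcomp(read), ref, PARAMS)}
        assert fwd["+"].score == rev["-"].score
        assert (fwd["+"].ref_start, fwd["+"].ref_end) == \
               (rev["-"].ref_start, rev["-"].ref_end)

    def test_score_includes_clip_penalty(self, rng):
        ref = random_seq(rng, 200)
        read = ref[50:90] + "A" * 10  # 40 matched + 10 clipped (likely)
        (aln,) = local_align(read, ref, PARAMS, strands="+")
        oracle = sw_softclip_oracle(read, ref, PARAMS)
        assert aln.score == oracle


class TestTrimming:
    def test_gap_separated_junk_block_removed(self, rng):
        ref = random_seq(rng, 200)
        # 30 true bases, then a fake indel path ending in a short echo block
        aln = ReadAlignment(read_id="r", ref_id="x", ref_start=50,
                            cigar=parse_cigar("30M1D8M12S"),
                            seq=ref[50:80] + "ACGTACGTACGTACGTACGT"[:20])
        trimmed = trim_terminal_gap_blocks(aln)
        assert str(trimmed.cigar) == "30M20S"
        assert trimmed.ref_start == 50

    def test_clean_alignment_untouched(self, rng):
        ref = random_seq(rng, 100)
        read = ref[10:60]
        (aln,) = local_align(read, ref, PARAMS, strands="+")
        assert trim_terminal_gap_blocks(aln, ref=ref) is aln

    def test_exact_reextension_restores_stolen_base(self, rng):
        # trimming plus re-extension against the reference recovers matches
        ref = random_seq(rng, 120)
        read = ref[20:60]
        aln = ReadAlignment(read_id="r", ref_id="x", ref_start=20,
                            cigar=parse_cigar("35M5S"), seq=read)
        extended = trim_terminal_gap_blocks(aln, ref=ref)
        assert str(extended.cigar) == "40M"


class TestSelectUnaligned:
    def make(self, read_id, mate=None, unmapped=False):
        status = AlnStatus.UNMAPPED if unmapped else AlnStatus.NONE
        cigar = Cigar() if unmapped else parse_cigar("10M")
        return ReadAlignment(read_id=read_id, mate=mate, status=status,
                             ref_id=None if unmapped else "g",
                             cigar=cigar, seq="A" * 10, qual="I" * 10)

    def test_single_end_keeps_unmapped_only(self):
        recs = [self.make("a", unmapped=True), self.make("b")]
        kept = select_unaligned(recs, "single")
        assert [r.read_id for r in kept] == ["a"]

    def test_single_end_partition_is_exact(self):
        recs = [self.make(f"r{i}", unmapped=bool(i % 2)) for i in range(10)]
        kept = select_unaligned(recs, "single")
        dropped = [r for r in recs if r not in kept]
        assert len(kept) + len(dropped) == len(recs)
        assert all(r.is_unmapped for r in kept)
        assert not any(r.is_unmapped for r in dropped)

    def test_paired_keeps_both_mates_when_one_unmapped(self):
        recs = [self.make("p", 1), self.make("p", 2, unmapped=True),
                self.make("q", 1), self.make("q", 2)]
        kept = select_unaligned(recs, "paired")
        assert [(r.read_id, r.mate) for r in kept] == [("p", 1), ("p", 2)]

    def test_paired_orphan_kept_with_warning(self, caplog):
        recs = [self.make("solo", 1, unmapped=True)]
        with caplog.at_level("WARNING"):
            kept = select_unaligned(recs, "paired")
        assert len(kept) == 1
        assert any("missing a mate" in r.message for r in caplog.records)


class TestSelectPartialHits:
    def aln(self, read_id, gene, cigar):
        return ReadAlignment(read_id=read_id, ref_id=gene, ref_start=0,
                             cigar=parse_cigar(cigar), seq="A" * 100)

    def test_clipped_read_is_pcc_candidate(self):
        sel = select_partial_hits([self.aln("r1", "EML4", "40S60M")], [],
                                  min_clip=8)
        assert sel.pcc == {"r1"}

    def test_full_match_retained_for_support_only(self):
        sel = select_partial_hits([self.aln("r2", "EML4", "100M")], [],
                                  min_clip=8)
        assert sel.pcc == set()
        assert sel.support == {"r2"}

    def test_unmapped_read_excluded(self):
        sel = select_partial_hits([], [], min_clip=8)
        assert sel.pcc == set() and sel.support == set()
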