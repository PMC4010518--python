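"""Junction classification: flank matching, adapter clipping, calling, frame."""


import pytest
from hypothesis import given, strategies as st

from fusiongrep.classify import (
    ClassifierParams,
    call_junction,
    classify_read,
    frame_check,
    match_flank_prefix,
    match_flank_suffix,
)
from fusiongrep.references import TranscriptReference, build_fusion_transcript, subseq
from fusiongrep.retrieval import AnchoredRead, AnchorSpec, SequencedRead, scan_reads

ANCHOR = "ATTTTGGATCATTGTTTGAC"
GENOMIC_FLANK = "GTAAAGGTTGCTTAGTTTCTCATTTCCATTTCTGTTTAATTTCTAG"  # CREBBP intron 1


def anchored(seq, read_id="x"):
    (ar,) = scan_reads([SequencedRead(read_id, seq)], AnchorSpec())
    return ar


class TestSuffixMatch:
    def test_exact_donor_flank_ends_at_breakpoint(self, kat6a_ref, params):
        end, mm = match_flank_suffix("AAGAAGAAGATGAAGAGTCAGATGATGCTGATG", kat6a_ref, params)
        assert (end, mm) == (3764, 0)

    def test_genomic_flank_matches_neither_reference(self, kat6a_ref, crebbp_ref, params):
        assert match_flank_suffix(GENOMIC_FLANK, kat6a_ref, params) is None
        assert match_flank_suffix(GENOMIC_FLANK, crebbp_ref, params) is None

    def test_terminal_flank_hits_window_end(self, kat6a_ref, crebbp_ref, params):
        for ref in (kat6a_ref, crebbp_ref):
            end, mm = match_flank_suffix(ref.sequence[-10:], ref, params)
            assert (end, mm) == (ref.window[1], 0)

    def test_flank_longer_than_window(self, kat6a_ref, params):
        assert match_flank_suffix("A" * 100, kat6a_ref, params) is None

    def test_tie_prefers_largest_end(self, params):
        ref = TranscriptReference("NM_T.1", "T", "ACGACGACG", 1)
        end, mm = match_flank_suffix("ACG", ref, params)
        assert (end, mm) == (9, 0)


class TestPrefixMatch:
    def test_adapter_clip_five(self, published_reads, crebbp_ref, params):
        # read ending ...GATACC|AGATC: 5 nt of adapter after the insert
        seq = published_reads["read13"]
        down = seq[seq.index(ANCHOR) + 20 :]
        pm = match_flank_prefix(down, crebbp_ref, 310, params)
        assert (pm.end, pm.mismatches, pm.adapter_clipped, pm.trailing_trimmed) == (341, 0, 5, 0)

    def test_internal_substitution_tolerated(self, published_reads, crebbp_ref, params):
        seq = published_reads["read11"]
        down = seq[seq.index(ANCHOR) + 20 :]
        pm = match_flank_prefix(down, crebbp_ref, 310, params)
        assert (pm.end, pm.mismatches, pm.adapter_clipped) == (351, 1, 0)

    def test_reference_extension_beats_ambiguous_adapter(self, published_reads, crebbp_ref, params):
        # ...ACCCA|GATC: the final AGATC could be adapter, but extending one
        # base further on the reference explains the read with 0 mismatches
        seq = published_reads["read22"]
        down = seq[seq.index(ANCHOR) + 20 :]
        pm = match_flank_prefix(down, crebbp_ref, 310, params)
        assert (pm.end, pm.adapter_clipped, pm.trailing_trimmed) == (343, 0, 4)

    def test_full_adapter_plus_noise_clipped(self, published_reads, crebbp_ref, params):
        # 24 nt tail: complete adapter stem then downstream adapter sequence
        seq = published_reads["read05"]
        down = seq[seq.index(ANCHOR) + 20 :]
        pm = match_flank_prefix(down, crebbp_ref, 310, params)
        assert (pm.end, pm.adapter_clipped) == (357, 24)

    def test_exact_copy_no_bookkeeping(self, crebbp_ref, params):
        down = subseq(crebbp_ref, 310, 349)
        pm = match_flank_prefix(down, crebbp_ref, 310, params)
        assert (pm.end, pm.mismatches, pm.adapter_clipped, pm.trailing_trimmed) == (349, 0, 0, 0)

    def test_garbage_tail_trimmed_to_anchor(self, crebbp_ref, params):
        pm = match_flank_prefix("GGGGGGGG", crebbp_ref, 310, params)
        assert pm.end == 309
        assert pm.trailing_trimmed == 8


class TestClassifyRead:
    def test_wildtype_example(self, published_reads, kat6a_ref, crebbp_ref, anchor_spec, params):
        cr = classify_read(anchored(published_reads["read01"]), [kat6a_ref], crebbp_ref, anchor_spec, params)
        assert cr.category == "WILDTYPE"
        assert cr.span_columns() == ("", "238-338 (exon 1-2)")

    def test_fusion_with_adapter_readthrough(self, published_reads, kat6a_ref, crebbp_ref, anchor_spec, params):
        cr = classify_read(anchored(published_reads["read05"]), [kat6a_ref], crebbp_ref, anchor_spec, params)
        assert cr.category == "FUSION"
        assert str(cr.donor_span) == "3756-3764 (exon 16)"
        assert str(cr.acceptor_span) == "290-357 (exon 2)"
        assert cr.adapter_clipped == 24

    def test_genomic_read_is_other(self, published_reads, kat6a_ref, crebbp_ref, anchor_spec, params):
        cr = classify_read(anchored(published_reads["read25"]), [kat6a_ref], crebbp_ref, anchor_spec, params)
        assert cr.category == "OTHER"
        assert cr.donor_span is None
        assert str(cr.acceptor_span) == "290-344 (exon 2)"

    def test_error_free_synthetic_junction_read(self, kat6a_ref, crebbp_ref, anchor_spec, params):
        fusion = build_fusion_transcript(kat6a_ref, 3764, crebbp_ref, 290)
        j = 3764 - kat6a_ref.coord_offset + 1
        read = fusion[j - 30 : j + 40]  # 30 nt donor flank, anchor, acceptor
        cr = classify_read(anchored(read), [kat6a_ref], crebbp_ref, anchor_spec, params)
        assert cr.category == "FUSION"
        assert cr.mismatches == 0
        assert cr.donor_span.end == 3764
        assert cr.donor_span.start == 3764 - 29

    def test_short_upstream_flank_uninformative(self, kat6a_ref, crebbp_ref, anchor_spec, params):
        cr = classify_read(anchored("ATG" + ANCHOR + "TTGGA"), [kat6a_ref], crebbp_ref, anchor_spec, params)
        assert cr.category == "UNINFORMATIVE"
        assert cr.donor_span is None

    def test_corrupt_anchor_offset_rejected(self, kat6a_ref, crebbp_ref, anchor_spec, params):
        ar = AnchoredRead(SequencedRead("x", "A" * 40), 3, "forward", "A" * 40)
        with pytest.raises(ValueError, match="corrupt"):
            classify_read(ar, [kat6a_ref], crebbp_ref, anchor_spec, params)

    def test_tie_break_prefers_wildtype(self, crebbp_ref, anchor_spec):
        # a decoy donor whose suffix equals the acceptor's pre-anchor bases
        decoy = TranscriptReference("NM_DECOY.1", "DECOY", "TT" + subseq(crebbp_ref, 270, 289), 1)
        read = subseq(crebbp_ref, 270, 289) + ANCHOR + subseq(crebbp_ref, 310, 330)
        cr = classify_read(anchored(read), [decoy], crebbp_ref, AnchorSpec(), ClassifierParams())
        assert cr.category == "WILDTYPE"
        cr2 = classify_read(
            anchored(read), [decoy], crebbp_ref, AnchorSpec(), ClassifierParams(tie_break="ambiguous")
        )
        assert cr2.category == "AMBIGUOUS"

    def test_categories_partition_and_bookkeeping(self, published_classified):
        assert len(published_classified) == 26
        for cr in published_classified:
            assert cr.category in ("FUSION", "WILDTYPE", "OTHER", "UNINFORMATIVE", "AMBIGUOUS")
            if cr.category in ("FUSION", "WILDTYPE"):
                assert cr.donor_span is not None
                total = (
                    cr.donor_span.length
                    + cr.acceptor_span.length
                    + cr.adapter_clipped
                    + cr.trailing_trimmed
                )
                assert total == 101

    def test_spans_reconstruct_reads(self, published_classified, published_reads, kat6a_ref, crebbp_ref):
        """Donor span + acceptor span + clipped tail reproduce the read up to
        the recorded mismatch count."""
        refs = {r.accession: r for r in (kat6a_ref, crebbp_ref)}
        for cr in published_classified:
            if cr.category not in ("FUSION", "WILDTYPE"):
                continue
            seq = published_reads[cr.read_id]
            d, a = cr.donor_span, cr.acceptor_span
            rebuilt = subseq(refs[d.accession], d.start, d.end) + subseq(refs[a.accession], a.start, a.end)
            matched_part = seq[: len(rebuilt)]
            mm = sum(1 for x, y in zip(rebuilt, matched_part) if x != y)
            assert mm == cr.mismatches
            assert len(rebuilt) + cr.adapter_clipped + cr.trailing_trimmed == len(seq)


class TestCallJunction:
    def test_packaged_reads_single_call(self, published_classified, kat6a_ref, crebbp_ref):
        calls = call_junction(published_classified, [kat6a_ref], crebbp_ref)
        assert len(calls) == 1
        c = calls[0]
        assert (c.donor_breakpoint, c.acceptor_start, c.supporting_reads) == (3764, 290, 11)
        assert (c.donor_gene, c.acceptor_gene) == ("KAT6A", "CREBBP")

    def test_empty_input(self):
        assert call_junction([]) == []

    def test_two_planted_junctions(self, kat6a_ref, crebbp_ref, anchor_spec, params):
        reads = []
        for bp, n in ((3764, 3), (3750, 2)):
            fusion = build_fusion_transcript(kat6a_ref, bp, crebbp_ref, 290)
            j = bp - kat6a_ref.coord_offset + 1
            for i in range(n):
                reads.append(SequencedRead(f"bp{bp}_{i}", fusion[j - 20 - i : j + 30]))
        classified = [
            classify_read(ar, [kat6a_ref], crebbp_ref, anchor_spec, params)
            for ar in scan_reads(reads, anchor_spec)
        ]
        calls = call_junction(classified, [kat6a_ref], crebbp_ref)
        assert [(c.donor_breakpoint, c.supporting_reads) for c in calls] == [(3764, 3), (3750, 2)]


def _coding_ref(acc, seq, cds_start, offset=1):
    return TranscriptReference(acc, acc.split("_")[0], seq, offset, cds_start=cds_start)


class TestFrameCheck:
    def _call(self, bp, acc_start):
        from fusiongrep.classify import JunctionCall

        return JunctionCall("NM_D.1", "D", bp, "", "NM_A.1", "A", acc_start, "", 1)

    def test_codon_boundary_join_in_frame(self):
        donor = _coding_ref("NM_D.1", "A" * 60, 10)  # L_d = 30 at bp 39
        acceptor = _coding_ref("NM_A.1", "C" * 60, 5)  # L_a = 6 at start 11
        call = frame_check(self._call(39, 11), donor, acceptor)
        assert call.frame == "in_frame"
        assert call.donor_codon == 10
        assert call.acceptor_codon == 3

    def test_one_base_shift_breaks_frame(self):
        donor = _coding_ref("NM_D.1", "A" * 60, 10)
        acceptor = _coding_ref("NM_A.1", "C" * 60, 5)
        assert frame_check(self._call(39, 12), donor, acceptor).frame == "out_of_frame"
        assert frame_check(self._call(40, 12), donor, acceptor).frame == "in_frame"

    @given(bp=st.integers(10, 58), acc=st.integers(5, 58))
    def test_frame_iff_codon_phases_agree(self, bp, acc):
        donor = _coding_ref("NM_D.1", "A" * 60, 10)
        acceptor = _coding_ref("NM_A.1", "C" * 60, 5)
        call = frame_check(self._call(bp, acc), donor, acceptor)
        ld, la = bp - 10 + 1, acc - 5
        assert call.frame == ("in_frame" if ld % 3 == la % 3 else "out_of_frame")

    def test_unknown_without_cds(self, kat6a_ref, crebbp_ref):
        call = frame_check(self._call(3764, 290), kat6a_ref, crebbp_ref)
        assert call.frame == "unknown"

    def test_breakpoint_upstream_of_cds(self):
        donor = _coding_ref("NM_D.1", "A" * 60, 50)
        acceptor = _coding_ref("NM_A.1", "C" * 60, 5)
        assert frame_check(self._call(20, 11), donor, acceptor).frame == "unknown"
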