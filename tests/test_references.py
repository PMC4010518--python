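"""Reference model: loading, coordinate access, consensus, fusion assembly."""


import pytest
from hypothesis import given, strategies as st

from fusiongrep.references import (
    ExonBound,
    TranscriptReference,
    build_fusion_transcript,
    consensus_from_anchored_reads,
    load_reference,
    subseq,
    write_reference,
)

ANCHOR = "ATTTTGGATCATTGTTTGAC"


def make_ref(seq, offset=1, exons=None, **kw):
    return TranscriptReference("NM_TEST.1", "TEST", seq, offset, exons or [], **kw)


class TestLoading:
    def test_fixture_anchor_base(self, crebbp_ref):
        # mRNA coordinate 290 is the first base of the exon-2 anchor
        assert crebbp_ref.base_at(290) == "A"
        assert subseq(crebbp_ref, 290, 309) == ANCHOR

    def test_fixture_windows(self, kat6a_ref, crebbp_ref):
        assert kat6a_ref.window == (3686, 3764)
        assert crebbp_ref.window == (212, 380)
        assert subseq(kat6a_ref, 3756, 3764) == "ATGCTGATG"

    def test_empty_fasta(self, tmp_path):
        fasta = tmp_path / "empty.fasta"
        fasta.write_text("")
        annot = tmp_path / "empty.tsv"
        annot.write_text("accession\tgene\tcoord_offset\texon_label\texon_start\texon_end\tcds_start\tcytoband\n")
        assert load_reference(fasta, annot) == {}

    def test_missing_annotation_names_accession(self, tmp_path):
        fasta = tmp_path / "r.fasta"
        fasta.write_text(">NM_X.1\nACGT\n")
        annot = tmp_path / "r.tsv"
        annot.write_text("accession\tgene\tcoord_offset\texon_label\texon_start\texon_end\tcds_start\tcytoband\n")
        with pytest.raises(ValueError, match="NM_X.1"):
            load_reference(fasta, annot)

    def test_overlapping_exons_rejected(self):
        make_ref("A" * 120, exons=[ExonBound("1", 1, 50), ExonBound("2", 51, 120)])
        with pytest.raises(ValueError, match="overlap"):
            make_ref("A" * 120, exons=[ExonBound("1", 1, 50), ExonBound("2", 45, 120)])

    def test_malformed_coordinates_report_line(self, tmp_path):
        fasta = tmp_path / "r.fasta"
        fasta.write_text(">NM_X.1\nACGT\n")
        annot = tmp_path / "r.tsv"
        annot.write_text(
            "accession\tgene\tcoord_offset\texon_label\texon_start\texon_end\tcds_start\tcytoband\n"
            "NM_X.1\tX\t1\t1\tone\t4\t\t\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            load_reference(fasta, annot)

    def test_write_load_round_trip(self, tmp_path, kat6a_ref, crebbp_ref):
        write_reference([kat6a_ref, crebbp_ref], tmp_path / "refs.fasta", tmp_path / "refs.tsv")
        refs = load_reference(tmp_path / "refs.fasta", tmp_path / "refs.tsv")
        again = refs[kat6a_ref.accession]
        assert again.sequence == kat6a_ref.sequence
        assert again.coord_offset == kat6a_ref.coord_offset
        assert again.exon_bounds == kat6a_ref.exon_bounds


class TestSubseq:
    def test_out_of_range_names_window(self, kat6a_ref):
        with pytest.raises(ValueError, match="3686-3764"):
            subseq(kat6a_ref, 3600, 3700)

    @given(data=st.data(), offset=st.integers(1, 500), n=st.integers(1, 80))
    def test_round_trip(self, data, offset, n):
        seq = data.draw(st.text("ACGT", min_size=n, max_size=n))
        ref = make_ref(seq, offset)
        s = data.draw(st.integers(offset, offset + n - 1))
        e = data.draw(st.integers(s, offset + n - 1))
        piece = subseq(ref, s, e)
        assert len(piece) == e - s + 1
        if e > s:
            mid = data.draw(st.integers(s, e - 1))
            assert subseq(ref, s, mid) + subseq(ref, mid + 1, e) == piece

    def test_single_base(self, crebbp_ref):
        w0, _ = crebbp_ref.window
        assert subseq(crebbp_ref, w0, w0) == crebbp_ref.sequence[0]


class TestExonLabels:
    def test_labels(self, crebbp_ref, kat6a_ref):
        assert crebbp_ref.exon_label_for(238, 338) == "exon 1-2"
        assert crebbp_ref.exon_label_for(290, 344) == "exon 2"
        assert kat6a_ref.exon_label_for(3732, 3764) == "exon 16"


class TestConsensus:
    def test_single_read_verbatim(self):
        res = consensus_from_anchored_reads([("GGACGTAC", 2)], "full", 100)
        assert res.sequence == "GGACGTAC"
        assert res.coord_offset == 98
        assert res.low_confidence == ()

    def test_zero_reads(self):
        with pytest.raises(ValueError):
            consensus_from_anchored_reads([], "full", 100)

    def test_tie_breaks_lexicographic_and_flagged(self):
        res = consensus_from_anchored_reads([("T", 1), ("G", 1)], "full", 50)
        assert res.sequence == "G"
        assert res.low_confidence == (49,)

    def test_n_does_not_vote(self):
        res = consensus_from_anchored_reads([("N", 1), ("T", 1)], "full", 50)
        assert res.sequence == "T"
        assert res.low_confidence == ()

    def test_upstream_side_right_justified(self):
        # upstream flanks end at coordinate anchor_start - 1
        res = consensus_from_anchored_reads(
            [("TTACG" + ANCHOR, 5), ("ACG" + ANCHOR, 3)], "upstream_of_anchor", 200
        )
        assert res.sequence == "TTACG"
        assert res.coord_offset == 195

    @given(data=st.data())
    def test_idempotence_on_error_free_reads(self, data):
        """Consensus of error-free reads equals the generating reference
        restricted to the covered columns."""
        n = data.draw(st.integers(30, 80))
        seq = data.draw(st.text("ACGT", min_size=n, max_size=n))
        ap = data.draw(st.integers(5, n - 5))  # anchor position, 0-based
        windows = [(0, n)]  # guarantee contiguous coverage
        for _ in range(data.draw(st.integers(1, 6))):
            s = data.draw(st.integers(0, ap))
            e = data.draw(st.integers(ap + 1, n))
            windows.append((s, e))
        reads = [(seq[s:e], ap - s) for s, e in windows]
        res = consensus_from_anchored_reads(reads, "full", 1000 + ap)
        assert res.sequence == seq
        assert res.coord_offset == 1000

    def test_published_set_reconstruction_matches_independent_counter(
        self, published_reads, published_truth, crebbp_ref, kat6a_ref
    ):
        """Packaged fixture references equal an independent per-column
        majority count over the packaged reads."""
        from collections import Counter, defaultdict

        votes_c = defaultdict(Counter)
        votes_k = defaultdict(Counter)
        for rid, seq in published_reads.items():
            cat = published_truth[rid]["category"]
            off = seq.index(ANCHOR)
            if cat == "WILDTYPE":
                for i, b in enumerate(seq):
                    votes_c[290 - off + i][b] += 1
            elif cat == "FUSION":
                for i, b in enumerate(seq[:off]):
                    votes_k[3764 - off + 1 + i][b] += 1
        expect_c = "".join(
            sorted(votes_c[c].items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            for c in sorted(votes_c)
        )
        expect_k = "".join(
            sorted(votes_k[c].items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            for c in sorted(votes_k)
        )
        assert min(votes_c) == 212 and max(votes_c) == 380
        assert min(votes_k) == 3686 and max(votes_k) == 3764
        assert crebbp_ref.sequence == expect_c
        assert kat6a_ref.sequence == expect_k


class TestFusionTranscript:
    def test_fixture_fusion_geometry(self, kat6a_ref, crebbp_ref):
        fusion = build_fusion_transcript(kat6a_ref, 3764, crebbp_ref, 290)
        assert len(fusion) == 79 + 91 == 170
        assert fusion[79 : 79 + 20] == ANCHOR  # positions 80-99, 1-based

    def test_single_base_donor_prefix(self, kat6a_ref, crebbp_ref):
        fusion = build_fusion_transcript(kat6a_ref, 3686, crebbp_ref, 290)
        assert fusion[0] == kat6a_ref.sequence[0]
        assert len(fusion) == 1 + 91

    def test_out_of_window_rejected(self, kat6a_ref, crebbp_ref):
        with pytest.raises(ValueError):
            build_fusion_transcript(kat6a_ref, 3800, crebbp_ref, 290)
        with pytest.raises(ValueError):
            build_fusion_transcript(kat6a_ref, 3764, crebbp_ref, 100)

    @given(k=st.integers(1, 20))
    def test_junction_contains_both_flanks(self, k, kat6a_ref, crebbp_ref):
        fusion = build_fusion_transcript(kat6a_ref, 3764, crebbp_ref, 290)
        expected = subseq(kat6a_ref, 3764 - k + 1, 3764) + subseq(crebbp_ref, 290, 290 + k - 1)
        j = 3764 - 3686 + 1  # donor bases in the chimera
        assert fusion[j - k : j + k] == expected
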