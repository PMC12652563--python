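"""Transcript models, coordinate maps, GTF/FASTA I/O."""

import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from translon import (
    ExonInterval,
    TranscriptModel,
    extract_spliced_sequence,
    genomic_to_transcript,
    read_fasta,
    read_gtf,
    transcript_to_genomic,
    write_feature_table,
    write_gtf,
)
from translon.annotation_io import read_feature_table, transcript_interval_to_genomic
from translon.nmd_features import NmdFeatureRecord, StopClass
from translon.orf_discovery import OrfAnnotation


def _model(exons, strand="+", tid="t", gid="g"):
    ivs = tuple(ExonInterval("chr1", s, e, strand) for s, e in exons)
    return TranscriptModel(tid, gid, "chr1", strand, ivs)


class TestModelValidation:
    def test_exon_requires_start_before_end(self):
        with pytest.raises(ValueError):
            ExonInterval("chr1", 10, 10, "+")

    def test_bad_strand_symbol(self):
        with pytest.raises(ValueError):
            ExonInterval("chr1", 0, 5, "strange")

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            _model([(0, 10), (5, 20)])

    def test_exon_order_must_match_strand(self):
        with pytest.raises(ValueError, match="transcript order"):
            _model([(20, 30), (0, 10)], strand="+")
        # the same genomic intervals are fine in minus-strand order
        m = _model([(20, 30), (0, 10)], strand="-")
        assert m.spliced_length == 20

    def test_junctions_are_prefix_sums(self):
        m = _model([(100, 150), (200, 250), (300, 320)])
        assert m.junctions == (50, 100)
        assert m.spliced_length == 120


class TestCoordinateMaps:
    def test_plus_strand_mapping(self):
        m = _model([(100, 150), (200, 250)])
        assert genomic_to_transcript(m, 200) == 50
        assert genomic_to_transcript(m, 100) == 0
        assert genomic_to_transcript(m, 175) is None  # intronic
        assert transcript_to_genomic(m, 50) == 200

    def test_minus_strand_mapping(self):
        m = _model([(200, 250), (100, 150)], strand="-")
        assert genomic_to_transcript(m, 249) == 0
        assert genomic_to_transcript(m, 100) == 99
        assert transcript_to_genomic(m, 0) == 249
        assert transcript_to_genomic(m, m.spliced_length - 1) == 100

    def test_out_of_range_transcript_position(self):
        m = _model([(0, 10)])
        with pytest.raises(ValueError):
            transcript_to_genomic(m, 10)

    @given(st.data())
    def test_round_trip_on_random_exon_chains(self, data):
        n_exons = data.draw(st.integers(1, 5))
        gaps = data.draw(
            st.lists(st.integers(1, 20), min_size=n_exons, max_size=n_exons)
        )
        lens = data.draw(
            st.lists(st.integers(1, 30), min_size=n_exons, max_size=n_exons)
        )
        strand = data.draw(st.sampled_from("+-"))
        exons, pos = [], 0
        for gap, ln in zip(gaps, lens):
            pos += gap
            exons.append((pos, pos + ln))
            pos += ln
        if strand == "-":
            exons = exons[::-1]
        m = _model(exons, strand=strand)
        for tpos in range(m.spliced_length):
            assert genomic_to_transcript(m, transcript_to_genomic(m, tpos)) == tpos


class TestExtraction:
    def test_plus_strand_splice(self):
        genome = {"chr1": "ATGCCCTAA"}
        m = _model([(0, 3), (6, 9)])
        s = extract_spliced_sequence(m, genome)
        assert s.seq == "ATGTAA"
        assert s.junctions == (3,)

    def test_minus_strand_reverse_complement(self):
        genome = {"chr1": "TTACAT"}
        m = _model([(0, 6)], strand="-")
        assert extract_spliced_sequence(m, genome).seq == "ATGTAA"

    def test_single_exon_has_no_junctions(self):
        genome = {"chr1": "ACGTACGT"}
        assert extract_spliced_sequence(_model([(0, 8)]), genome).junctions == ()

    def test_exon_beyond_chromosome_is_an_error(self):
        with pytest.raises(ValueError, match="t"):
            extract_spliced_sequence(_model([(0, 10)]), {"chr1": "ACGT"})

    @given(st.data())
    def test_minus_extraction_is_reverse_complement_of_plus(self, data):
        genome_seq = data.draw(
            st.text(alphabet="ACGT", min_size=40, max_size=120)
        )
        genome = {"chr1": genome_seq}
        n = data.draw(st.integers(1, 4))
        cuts = sorted(
            data.draw(
                st.lists(
                    st.integers(0, len(genome_seq)),
                    min_size=2 * n,
                    max_size=2 * n,
                    unique=True,
                )
            )
        )
        exons = [(cuts[2 * i], cuts[2 * i + 1]) for i in range(n)]
        exons = [(s, e) for s, e in exons if s < e]
        if not exons:
            return
        plus = extract_spliced_sequence(_model(exons), genome)
        minus = extract_spliced_sequence(_model(exons[::-1], strand="-"), genome)
        assert minus.seq == str(Seq(plus.seq).reverse_complement())


class TestFasta:
    def test_case_normalization_and_multiline(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">chr1 some description\nacgt\nACGT\n>chr2\nTTTT\n")
        genome = read_fasta(p)
        assert genome == {"chr1": "ACGTACGT", "chr2": "TTTT"}

    def test_duplicate_record_name_is_an_error(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">chr1\nACGT\n>chr1\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)


class TestGtfRead:
    def test_single_exon_coordinate_convention(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        genes = read_gtf(p)
        (t,) = genes["g"]
        assert t.exons[0].start == 100 and t.exons[0].end == 200
        assert t.spliced_length == 100

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_two_exons_sorted_into_transcript_order(self, tmp_path, strand):
        p = tmp_path / "a.gtf"
        rows = [
            f'chr1\tsrc\texon\t101\t150\t.\t{strand}\t.\tgene_id "g"; transcript_id "t";',
            f'chr1\tsrc\texon\t201\t250\t.\t{strand}\t.\tgene_id "g"; transcript_id "t";',
        ]
        p.write_text("\n".join(rows) + "\n")
        (t,) = read_gtf(p)["g"]
        assert t.junctions == (50,)
        first = t.exons[0]
        assert first.start == (100 if strand == "+" else 200)

    def test_gff3_attribute_dialect_accepted(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text("chr1\tsrc\texon\t1\t50\t.\t+\t.\tgene_id=g;transcript_id=t\n")
        (t,) = read_gtf(p)["g"]
        assert t.transcript_id == "t" and t.spliced_length == 50

    def test_missing_transcript_id_is_a_parse_error(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\tsrc\texon\t1\t50\t.\t+\t.\tgene_id "g";\n')
        with pytest.raises(ValueError, match="transcript_id"):
            read_gtf(p)

    def test_mixed_strand_transcript_is_a_validation_error(self, tmp_path):
        p = tmp_path / "a.gtf"
        rows = [
            'chr1\tsrc\texon\t1\t50\t.\t+\t.\tgene_id "g"; transcript_id "t";',
            'chr1\tsrc\texon\t101\t150\t.\t-\t.\tgene_id "g"; transcript_id "t";',
        ]
        p.write_text("\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="mixed"):
            read_gtf(p)


class TestGtfWrite:
    def test_round_trip_models_and_cds(self, tmp_path):
        genome = {"chr1": "CCATGAAAGG" + "CCCC" + "TTAACC"}
        m = _model([(0, 10), (14, 20)], tid="t", gid="g")
        seq = extract_spliced_sequence(m, genome)
        from translon.orf_discovery import longest_orf

        orf = longest_orf(seq, 1)
        assert orf.has_stop
        out = tmp_path / "out.gtf"
        write_gtf({"g": [m]}, {"t": orf}, out)
        genes, cds = read_gtf(out, with_cds=True)
        (t2,) = genes["g"]
        assert t2.exons == m.exons
        # CDS spans cover ORF minus stop codon
        assert sum(e - s for s, e in cds["t"]) == orf.cds_length - 3

    def test_orf_spanning_junction_gets_frame_columns(self, tmp_path):
        genome = {"chr1": "ATGAA" + "CCCC" + "ATAACC"}
        m = _model([(0, 5), (9, 15)], tid="t", gid="g")
        seq = extract_spliced_sequence(m, genome)
        assert seq.seq.startswith("ATGAAATAA")
        orf = OrfAnnotation("t", 0, 9, True, "MK")
        out = tmp_path / "out.gtf"
        write_gtf({"g": [m]}, {"t": orf}, out)
        cds_lines = [
            l.split("\t") for l in out.read_text().splitlines() if l.split("\t")[2] == "CDS"
        ]
        # frame = (3 - cumulative CDS nt mod 3) mod 3 per segment
        assert [(l[3], l[4], l[7]) for l in cds_lines] == [
            ("1", "5", "0"),
            ("10", "10", "1"),
        ]

    def test_noncoding_transcript_writes_exons_only(self, tmp_path):
        genome = {"chr1": "CCCCCCCCCC"}
        m = _model([(0, 10)], tid="t", gid="g")
        out = tmp_path / "out.gtf"
        write_gtf({"g": [m]}, {"t": None}, out)
        feats = {l.split("\t")[2] for l in out.read_text().splitlines()}
        assert feats == {"exon"}

    def test_unknown_transcript_orf_is_an_error(self, tmp_path):
        m = _model([(0, 10)], tid="t", gid="g")
        with pytest.raises(ValueError, match="unknown"):
            write_gtf({"g": [m]}, {"other": OrfAnnotation("other", 0, 3, False, "M")}, tmp_path / "o.gtf")

    def test_interval_projection_minus_strand(self):
        m = _model([(20, 30), (0, 10)], strand="-")
        # transcript [5, 15) crosses the junction
        segs = transcript_interval_to_genomic(m, 5, 15)
        assert segs == [(20, 25), (5, 10)]


class TestFeatureTable:
    def _record(self, cls=StopClass.NORMAL, dist=None, n=0):
        return NmdFeatureRecord("t1", "g1", cls, 10, 20, dist, n, True, "MK")

    def test_empty_collection_writes_header_only(self, tmp_path):
        p = tmp_path / "f.csv"
        write_feature_table([], p)
        assert p.read_text().strip().startswith("transcript_id,gene_id,stop_class")
        assert len(p.read_text().strip().splitlines()) == 1

    def test_normal_record_has_empty_dej_distance(self, tmp_path):
        p = tmp_path / "f.csv"
        write_feature_table([self._record()], p)
        df = read_feature_table(p)
        row = df.loc["t1"]
        assert row["stop_class"] == "Normal"
        assert row.isna()["dist_stop_to_last_dEJ"]
        assert row["Translation"] == "MK"

    def test_ptc_record_round_trips_distance(self, tmp_path):
        p = tmp_path / "f.csv"
        write_feature_table([self._record(StopClass.PTC_DEJ, 70, 1)], p)
        df = read_feature_table(p)
        assert df.loc["t1", "dist_stop_to_last_dEJ"] == 70
        assert df.loc["t1", "stop_class"] == "PTC_dEJ"
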