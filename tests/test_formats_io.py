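"""File formats: signal container, SAM/PAF tags, BED, pore models."""

import numpy as np
import pytest

import sigpile as sp
from sigpile import formats_io as fio


class TestSignalContainer:
    def test_identity_calibration(self, tmp_path):
        sig = sp.RawSignal("r1", np.array([0, 1, 2]), 8192, 0, 8192)
        assert sig.to_pA().tolist() == [0, 1, 2]

    def test_offset_and_scale(self):
        sig = sp.RawSignal("r1", np.array([0]), 1000, 10, 1000)
        assert sig.to_pA().tolist() == [10.0]

    def test_round_trip(self, tmp_path, dataset):
        path = tmp_path / "sig.tsv"
        sp.write_signal_container(path, [r.signal for r in dataset.reads])
        back = sp.read_signal_container(path)
        assert set(back) == {r.signal.read_id for r in dataset.reads}
        for r in dataset.reads:
            got = back[r.signal.read_id]
            np.testing.assert_array_equal(got.samples, r.signal.samples)
            assert got.digitisation == r.signal.digitisation
            assert got.range_pA == r.signal.range_pA

    def test_duplicate_read_id_rejected(self, tmp_path):
        path = tmp_path / "sig.tsv"
        line = "r1\t8192\t0\t8192\t4000\t1,2,3\n"
        path.write_text(line + line)
        with pytest.raises(fio.FormatError, match="duplicate"):
            sp.read_signal_container(path)

    def test_missing_calibration_names_read(self, tmp_path):
        path = tmp_path / "sig.tsv"
        path.write_text("r9\t\t0\t8192\t4000\t1,2\n")
        with pytest.raises(fio.FormatError, match="r9"):
            sp.read_signal_container(path)


class TestSamPaf:
    def _one_record(self):
        rec = sp.ReadRecord("r1", sequence="ACGTA", ref_name="ref1",
                            ref_start=9, cigar="5M", strand="+")
        rec.set_tag("ss", "3,4,2,5,6,", "Z")
        rec.set_tag("si", "0,20,0,5", "Z")
        return rec

    def test_ss_tag_survives_sam_round_trip(self, tmp_path):
        path = tmp_path / "a.sam"
        sp.write_alignments(path, [self._one_record()], {"ref1": 100})
        back = sp.read_alignments(path)
        assert len(back) == 1
        assert back[0].get_tag("ss") == "3,4,2,5,6,"
        assert back[0].get_tag("si") == "0,20,0,5"
        assert back[0].ref_start == 9  # 0-based restored from SAM's 1-based POS

    def test_sam_and_paf_agree(self, tmp_path):
        truth = self._one_record()
        sam, paf = tmp_path / "a.sam", tmp_path / "a.paf"
        sp.write_alignments(sam, [truth], {"ref1": 100})
        sp.write_alignments(paf, [truth], {"ref1": 100})
        from_sam, from_paf = sp.read_alignments(sam)[0], sp.read_alignments(paf)[0]
        for attr in ("read_id", "ref_name", "ref_start", "strand", "cigar"):
            assert getattr(from_sam, attr) == getattr(from_paf, attr), attr
        assert from_sam.get_tag("ss") == from_paf.get_tag("ss")
        assert from_sam.get_tag("si") == from_paf.get_tag("si")

    def test_region_filter_matches_full_scan(self, tmp_path, dataset):
        path = tmp_path / "a.sam"
        recs = [r.record for r in dataset.reads]
        sp.write_alignments(path, recs, {"ref1": len(dataset.reference)})
        region = sp.Region("ref1", 100, 150)
        fast = sp.read_alignments(path, region)
        scan = [r for r in sp.read_alignments(path)
                if r.ref_name == "ref1" and r.ref_start < 150 and r.ref_end > 100]
        assert [r.read_id for r in fast] == [r.read_id for r in scan]
        assert len(fast) > 0

    def test_move_table_tag_round_trip(self, tmp_path, dataset):
        path = tmp_path / "a.sam"
        rec = dataset.reads[0].record
        sp.write_alignments(path, [rec], {"ref1": len(dataset.reference)})
        back = sp.read_alignments(path)[0]
        assert list(back.get_tag("mv")) == list(rec.get_tag("mv"))
        assert back.get_tag("ts") == rec.get_tag("ts")

    def test_malformed_cigar_is_hard_error(self):
        with pytest.raises(fio.FormatError, match="CIGAR"):
            fio.parse_cigar("5M3")


class TestAlignmentTags:
    def test_attach_extract_round_trip(self, dataset):
        r = dataset.reads[0]
        rec = fio.attach_alignment(r.record, r.sig2ref)
        back = fio.extract_alignment(rec, seq_kind="reference")
        assert back == r.sig2ref


class TestBed:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t5\t6\tCpG\n")
        track = sp.read_bed(p)
        (region, label, color), = track.intervals
        assert (region.start, region.end, label) == (5, 6, "CpG")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert sp.read_bed(p).intervals == []

    def test_unsorted_input_sorted(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t50\t60\tb\nchr1\t5\t6\ta\n")
        track = sp.read_bed(p)
        assert [iv[1] for iv in track.intervals] == ["a", "b"]

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t6\t5\tx\n")
        with pytest.raises(fio.FormatError):
            sp.read_bed(p)


class TestPoreModel:
    def test_complete_model_round_trip(self, tmp_path, small_model):
        p = tmp_path / "model.tsv"
        sp.write_pore_model(p, small_model)
        back = sp.read_pore_model(p)
        assert back.k == small_model.k
        assert back.complete
        assert back.levels == small_model.levels

    def test_row_count(self, tmp_path, small_model):
        assert len(small_model) == 4 ** small_model.k

    def test_duplicate_kmer_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("kmer\tlevel_mean\tlevel_stdv\nAAA\t80\t2\nAAA\t81\t2\n")
        with pytest.raises(fio.FormatError, match="duplicate"):
            sp.read_pore_model(p)

    def test_mixed_k_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("kmer\tlevel_mean\tlevel_stdv\nAAA\t80\t2\nAAAA\t81\t2\n")
        with pytest.raises(fio.FormatError, match="mixed"):
            sp.read_pore_model(p)

    def test_missing_kmers_warn_incomplete(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("kmer\tlevel_mean\tlevel_stdv\nAA\t80\t2\nAC\t81\t2\n")
        with pytest.warns(UserWarning, match="incomplete"):
            model = sp.read_pore_model(p)
        assert not model.complete


class TestRegion:
    def test_parse_region_is_one_based_inclusive(self):
        r = sp.parse_region("chr1:101-200")
        assert (r.ref_name, r.start, r.end) == ("chr1", 100, 200)

    def test_bad_region_rejected(self):
        with pytest.raises(fio.FormatError):
            sp.parse_region("chr1:banana")
        with pytest.raises(fio.FormatError):
            sp.Region("x", 7, 7)


class TestFasta:
    def test_write_read(self, tmp_path, dataset):
        p = tmp_path / "ref.fa"
        sp.write_fasta(p, {"ref1": dataset.reference})
        assert sp.read_fasta(p)["ref1"] == dataset.reference
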