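"""Layout geometry: time-scale, molecule-scale, pileup assembly."""

import numpy as np
import pytest

import sigpile as sp
from sigpile.pileup import (
    PileupOptions, build_pileup, clip_to_region,
    layout_molecule_scale, layout_time_scale,
)

M, I, D = sp.match, sp.sig_ins, sp.base_del


def identity_signal(n, read_id="r1"):
    """pA value == sample index, so geometry is easy to read off."""
    return sp.RawSignal(read_id, np.arange(n, dtype=float), 1000, 0, 1000)


class TestTimeScale:
    def test_uniform_sample_spacing(self):
        aln = sp.SsAlignment("r1", (M(4), M(6)), 0, 10, 0, 2)
        g = layout_time_scale(aln, identity_signal(10), "AC")
        assert [x for x, _ in g.polyline] == [float(i) for i in range(10)]

    def test_base_boundaries_at_cumulative_dwells(self):
        aln = sp.SsAlignment("r1", (M(3), M(5), M(2)), 0, 10, 0, 3)
        g = layout_time_scale(aln, identity_signal(10), "ACG")
        assert [(c[0], c[1]) for c in g.columns] == [(0, 3), (3, 8), (8, 10)]
        assert [c[2] for c in g.columns] == ["A", "C", "G"]

    def test_sample_count_conserved(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 15))
            dwells = rng.integers(1, 9, n)
            ops = tuple(M(int(d)) for d in dwells)
            total = int(dwells.sum())
            aln = sp.SsAlignment("r1", ops, 0, total, 0, n)
            g = layout_time_scale(aln, identity_signal(total))
            assert g.n_samples == aln.signal_samples


class TestMoleculeScale:
    def test_placement_formula(self):
        aln = sp.SsAlignment("r1", (M(3), M(6)), 0, 9, 0, 2)
        g = layout_molecule_scale(aln, identity_signal(9), "AC", base_width=12)
        xs = [x for x, _ in g.polyline]
        assert xs[:3] == [2.0, 6.0, 10.0]
        assert xs[3:] == [13.0, 15.0, 17.0, 19.0, 21.0, 23.0]

    def test_equal_column_widths(self):
        aln = sp.SsAlignment("r1", (M(1), M(7), M(3)), 0, 11, 0, 3)
        g = layout_molecule_scale(aln, identity_signal(11), "ACG", base_width=20)
        widths = {x1 - x0 for x0, x1, _ in g.columns}
        assert widths == {20.0}

    def test_deletion_gap_labelled(self):
        aln = sp.SsAlignment("r1", (M(3), D(1), M(3)), 0, 6, 0, 3)
        g = layout_molecule_scale(aln, identity_signal(6), "ACG", base_width=10)
        (x0, x1, labels), = g.gap_spans
        assert (x0, x1) == (10.0, 20.0)  # exactly one column
        assert labels == "C"

    def test_insertion_marker_at_preceding_border(self):
        aln = sp.SsAlignment("r1", (M(2), I(3), M(2)), 0, 7, 0, 2)
        g = layout_molecule_scale(aln, identity_signal(7), "AC", base_width=10)
        (x, vals), = g.insertion_markers
        assert x == 10.0  # border between column 0 and column 1
        assert vals == [2.0, 3.0, 4.0]

    def test_samples_per_column_equals_dwell(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(1, 20))
            dwells = rng.integers(1, 10, n)
            ops = tuple(M(int(d)) for d in dwells)
            total = int(dwells.sum())
            aln = sp.SsAlignment("r1", ops, 0, total, 0, n)
            g = layout_molecule_scale(aln, identity_signal(total), "A" * n, 24.0)
            for (x0, x1, _), d in zip(g.columns, dwells):
                inside = [x for x, _ in g.polyline if x0 < x < x1]
                assert len(inside) == d


class TestClipToRegion:
    def test_whole_columns_kept(self, dataset):
        region = sp.Region("ref1", 100, 140)
        aln = next(a for a in dataset.sig2ref_truth
                   if a.seq_start < 100 and a.seq_end > 140)
        clipped = clip_to_region(aln, region)
        assert clipped.seq_start >= 100 and clipped.seq_end <= 140
        assert sp.validate(clipped, 10**9, 10**9) == []

    def test_disjoint_returns_none(self, dataset):
        aln = dataset.sig2ref_truth[0]
        far = sp.Region("ref1", aln.seq_end + 10, aln.seq_end + 20) \
            if aln.seq_end + 20 <= len(dataset.reference) else \
            sp.Region("ref1", 0, max(1, aln.seq_start))
        if far.end <= aln.seq_start or far.start >= aln.seq_end:
            assert clip_to_region(aln, far) is None


class TestBuildPileup:
    def test_strand_tracks_and_overlay(self, dataset):
        region = sp.Region("ref1", 50, 150)
        layout = build_pileup(region, dataset.sig2ref_truth, dataset.signals,
                              dataset.reference)
        kinds = [(t.kind, t.strand) for t in layout.tracks]
        assert kinds == [("pileup_overlay", "+"), ("stacked_reads", "+"),
                         ("pileup_overlay", "-"), ("stacked_reads", "-")]
        n_plus = sum(1 for a in dataset.sig2ref_truth
                     if a.strand == "+" and a.seq_start < 150 and a.seq_end > 50)
        stack_plus = next(t for t in layout.tracks
                          if t.kind == "stacked_reads" and t.strand == "+")
        assert len(stack_plus.members) == n_plus

    def test_deselect_empties_overlay_not_stack(self, dataset):
        region = sp.Region("ref1", 50, 150)
        layout = build_pileup(region, dataset.sig2ref_truth, dataset.signals,
                              dataset.reference,
                              PileupOptions(selected_reads=[]))
        for t in layout.tracks:
            if t.kind == "pileup_overlay":
                assert t.members == []
            if t.kind == "stacked_reads":
                assert len(t.members) > 0 or t.strand == "-"

    def test_empty_region_warns(self, dataset):
        region = sp.Region("ref1", 1, 2)
        empty = [a for a in dataset.sig2ref_truth if a.seq_start >= 2]
        with pytest.warns(UserWarning, match="no reads overlap"):
            layout = build_pileup(region, [], dataset.signals, dataset.reference)
        assert layout.glyphs == {}

    def test_column_width_invariance_across_glyphs(self, dataset):
        region = sp.Region("ref1", 40, 160)
        layout = build_pileup(region, dataset.sig2ref_truth, dataset.signals,
                              dataset.reference)
        bw = layout.base_width
        for g in layout.glyphs.values():
            for x0, x1, _ in g.columns:
                assert x1 - x0 == pytest.approx(bw)

    def test_every_sample_appears_exactly_once(self, dataset):
        region = sp.Region("ref1", 40, 160)
        layout = build_pileup(region, dataset.sig2ref_truth, dataset.signals,
                              dataset.reference)
        for aln in dataset.sig2ref_truth:
            clipped = clip_to_region(aln, region)
            if clipped is None:
                continue
            g = layout.glyphs[aln.read_id]
            assert g.n_samples == clipped.signal_samples

    def test_minus_columns_coincide_with_plus_columns(self, dataset):
        region = sp.Region("ref1", 40, 160)
        layout = build_pileup(region, dataset.sig2ref_truth, dataset.signals,
                              dataset.reference)
        plus_cols = {}
        for g in layout.glyphs.values():
            if g.strand == "+":
                for x0, x1, _ in g.columns:
                    plus_cols[round(x0, 9)] = x1
        checked = 0
        for g in layout.glyphs.values():
            if g.strand == "-":
                for x0, x1, _ in g.columns:
                    if round(x0, 9) in plus_cols:
                        assert plus_cols[round(x0, 9)] == x1
                        checked += 1
        assert checked > 0

    def test_stacked_rows_never_overlap(self, dataset):
        region = sp.Region("ref1", 0, len(dataset.reference))
        layout = build_pileup(region, dataset.sig2ref_truth, dataset.signals,
                              dataset.reference)
        for t in layout.tracks:
            if t.kind != "stacked_reads":
                continue
            by_row = {}
            for rid, row in t.rows.items():
                g = layout.glyphs[rid]
                x0 = min(c[0] for c in g.columns)
                x1 = max(c[1] for c in g.columns)
                for a, b in by_row.get(row, []):
                    assert x1 <= a or x0 >= b
                by_row.setdefault(row, []).append((x0, x1))

    def test_annotation_and_simulated_tracks_appended(self, dataset, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("ref1\t60\t61\tCpG\n")
        sim = [(dataset.sig2ref_truth[0], dataset.reads[0].signal)]
        region = sp.Region("ref1", 40, 160)
        layout = build_pileup(region, dataset.sig2ref_truth, dataset.signals,
                              dataset.reference,
                              PileupOptions(annotations=sp.read_bed(bed),
                                            simulated=sim))
        kinds = [t.kind for t in layout.tracks]
        assert kinds[:2] == ["annotation", "simulated"]
        assert len(layout.annotations) == 1

    def test_total_width(self, dataset):
        region = sp.Region("ref1", 10, 60)
        layout = build_pileup(region, dataset.sig2ref_truth, dataset.signals,
                              dataset.reference, PileupOptions(base_width=7.0))
        assert layout.width == 50 * 7.0
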