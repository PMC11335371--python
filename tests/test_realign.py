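"""Projection of signal-to-read alignments through read-to-reference CIGARs."""

import numpy as np
import pytest

import sigpile as sp
from sigpile.realign import RealignError, ensure_oriented, orient_for_reference, realign
from sigpile.ss_codec import OpKind, sample_slices

M, I, D = sp.match, sp.sig_ins, sp.base_del


def make_case(dwells, cigar, strand="+", ref_start=10, trim=0, read_id="r1"):
    L = len(dwells)
    sig2read = sp.SsAlignment(
        read_id, tuple(M(d) for d in dwells), trim, trim + sum(dwells),
        0, L, "read", strand, "forward")
    rec = sp.ReadRecord(read_id, sequence="A" * L, ref_name="ref1",
                        ref_start=ref_start, cigar=cigar, strand=strand)
    return sig2read, rec


# ---------------------------------------------------------------------------
# independent per-sample projection oracle
# ---------------------------------------------------------------------------

def per_sample_oracle(dwells, trim, cigar, strand, ref_start):
    """Map every sample to ('ref', pos), ('ins', anchor ref pos) or 'clip',
    one sample at a time, with no shared code with realign."""
    L = len(dwells)
    starts = trim + np.concatenate([[0], np.cumsum(dwells)[:-1]])
    base_label = {}
    del_positions = []
    q, r = 0, ref_start
    from sigpile.formats_io import parse_cigar
    for op, n in parse_cigar(cigar):
        for _ in range(n):
            if op in "M=X":
                base_label[q] = ("ref", r); q += 1; r += 1
            elif op == "I":
                base_label[q] = ("ins", r); q += 1
            elif op == "S":
                base_label[q] = "clip"; q += 1
            elif op in "DN":
                del_positions.append(r); r += 1
    sample_label = {}
    for i in range(L):  # i = sequencing index; q = alignment query index
        qi = i if strand == "+" else L - 1 - i
        for s in range(starts[i], starts[i] + dwells[i]):
            sample_label[s] = base_label[qi]
    return sample_label, del_positions


def expand_output(aln):
    """Flatten a signal-to-reference alignment back to per-sample labels."""
    o = ensure_oriented(aln)
    out = {}
    dels = []
    pos = o.seq_start
    for op, sl in zip(o.ops, sample_slices(o)):
        if op.kind is OpKind.MATCH:
            for s in range(*sl):
                out[s] = ("ref", pos)
            pos += 1
        elif op.kind is OpKind.BASE_DEL:
            dels.extend(range(pos, pos + op.length))
            pos += op.length
        else:
            for s in range(*sl):
                out[s] = ("ins", pos)
    return out, dels


class TestWorkedExamples:
    def test_identity_projection(self):
        s2r, rec = make_case([3, 3, 3, 3, 3], "5M")
        out = realign(s2r, rec)
        assert sp.emit_ss(out) == "3,3,3,3,3,"
        assert (out.seq_start, out.seq_end) == (10, 15)
        assert out.seq_kind == "reference"

    def test_insertion_stacks_samples(self):
        s2r, rec = make_case([3, 3, 4, 3, 3], "2M1I2M")
        assert sp.emit_ss(realign(s2r, rec)) == "3,3,4I3,3,"

    def test_deletion_leaves_gap(self):
        s2r, rec = make_case([3, 3, 3, 3], "2M1D2M")
        assert sp.emit_ss(realign(s2r, rec)) == "3,3,1D3,3,"

    def test_soft_clips_trim_signal_span(self):
        s2r, rec = make_case([2, 2, 5, 5, 5, 3], "2S3M1S")
        out = realign(s2r, rec)
        assert sp.emit_ss(out) == "5,5,5,"
        assert (out.sig_start, out.sig_end) == (4, 19)

    def test_hard_clip_rejected(self):
        s2r, rec = make_case([3, 3], "2M2H")
        with pytest.raises(RealignError, match="hard-clip"):
            realign(s2r, rec)

    def test_cigar_length_mismatch_rejected(self):
        s2r, rec = make_case([3, 3, 3], "5M")
        with pytest.raises(RealignError):
            realign(s2r, rec)

    def test_minus_strand_ops_run_against_reference(self):
        s2r, rec = make_case([2, 3, 4], "3M", strand="-")
        out = realign(s2r, rec)
        # sequencing order: base 0 (= rightmost ref base) first
        assert sp.emit_ss(out) == "2,3,4,"
        oriented = orient_for_reference(out)
        assert sp.emit_ss(sp.SsAlignment("x", oriented.ops, 0, 9, 0, 3)) == "4,3,2,"


class TestOrient:
    def test_plus_is_identity(self):
        aln = sp.SsAlignment("r", (M(3), M(5)), 0, 8, 0, 2, "reference", "+")
        assert orient_for_reference(aln) is aln

    def test_minus_reverses_and_flips(self):
        aln = sp.SsAlignment("r", (M(3), M(5), M(2)), 0, 10, 0, 3,
                             "reference", "-", "forward")
        out = orient_for_reference(aln)
        assert [op.length for op in out.ops] == [2, 5, 3]
        assert out.signal_direction == "reverse"

    def test_involution_on_fuzzed_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(1, 20))
            dwells = rng.integers(1, 9, n)
            aln = sp.SsAlignment("r", tuple(M(int(d)) for d in dwells),
                                 0, int(dwells.sum()), 0, n, "reference", "-",
                                 "forward")
            assert orient_for_reference(orient_for_reference(aln)) == aln


def random_cigar(rng, L):
    """Random CIGAR consuming exactly L query bases, M-anchored at both ends."""
    c1 = int(rng.integers(0, min(4, L)))
    c2 = int(rng.integers(0, min(4, L - c1)))
    mid = L - c1 - c2
    if mid < 1:
        c1 = c2 = 0
        mid = L
    units = ["M"]
    budget = mid - 1
    while budget > 0:
        u = rng.choice(["M", "M", "M", "I", "D", "N"])
        if u in "DN":
            units.append(u)
            continue
        units.append(u)
        budget -= 1
    if units[-1] != "M":   # end anchored on a reference-consuming query base
        units.append("M")
        # steal a query unit: drop one interior M (guaranteed: first unit)
        for j in range(len(units) - 2, -1, -1):
            if units[j] == "M" and sum(u in "MI" for u in units) > mid:
                units.pop(j)
                break
    # merge into a string
    while sum(u in "MI" for u in units) > mid:
        for j, u in enumerate(units):
            if u == "I":
                units.pop(j)
                break
        else:
            break
    parts = ["%dS" % c1] if c1 else []
    run, prev = 0, None
    for u in units:
        if u == prev:
            run += 1
        else:
            if prev:
                parts.append(f"{run}{prev}")
            run, prev = 1, u
    parts.append(f"{run}{prev}")
    if c2:
        parts.append("%dS" % c2)
    return "".join(parts)


class TestOracleEquivalence:
    def test_fuzzed_projection_matches_per_sample_oracle(self):
        rng = np.random.default_rng(2718)
        n_checked = 0
        while n_checked < 500:
            L = int(rng.integers(2, 40))
            cigar = random_cigar(rng, L)
            from sigpile.formats_io import parse_cigar
            if sum(n for op, n in parse_cigar(cigar) if op in "MIS") != L:
                continue
            dwells = [int(d) for d in rng.integers(1, 13, L)]
            trim = int(rng.integers(0, 30))
            strand = "+" if rng.random() < 0.5 else "-"
            ref_start = int(rng.integers(0, 100))
            s2r, rec = make_case(dwells, cigar, strand, ref_start, trim)
            out = realign(s2r, rec)

            got, got_dels = expand_output(out)
            want, want_dels = per_sample_oracle(dwells, trim, cigar, strand, ref_start)
            non_clip = {s: lab for s, lab in want.items() if lab != "clip"}
            assert got == non_clip, cigar
            assert sorted(got_dels) == sorted(want_dels), cigar

            # conservation: output samples = input minus clipped
            n_clip = sum(1 for lab in want.values() if lab == "clip")
            assert out.signal_samples == sum(dwells) - n_clip
            ref_len = sum(n for op, n in parse_cigar(cigar) if op in "MDN=X")
            assert out.n_match + sum(op.length for op in out.ops
                                     if op.kind is OpKind.BASE_DEL) == ref_len
            assert sp.validate(out, trim + sum(dwells) + 10, 10_000) == []
            n_checked += 1


class TestSimulatorEndToEnd:
    def test_error_free_bundle_recovered_exactly(self, dataset):
        from sigpile.reform import reform
        for r in dataset.reads:
            s2ref = realign(reform(r.move_table, r.record, r.signal), r.record)
            assert s2ref == r.sig2ref

    def test_injected_errors_still_validate(self, dataset):
        from sigpile.reform import reform
        err = sp.inject_errors(dataset, sub_rate=0.05, ins_rate=0.05,
                               del_rate=0.05, max_softclip=6, seed=3)
        for r in err.reads:
            out = realign(reform(r.move_table, r.record), r.record)
            assert sp.validate(out, len(r.signal), len(dataset.reference)) == []
            assert out == r.sig2ref
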