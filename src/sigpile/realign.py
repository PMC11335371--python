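"""Project signal-to-read alignments onto the reference.

``realign`` composes two alignments: the signal-to-read alignment produced by
:func:`sigpile.reform.reform` (or any producer of the ss dialect) and the
read-to-reference CIGAR from the read's SAM record.  The result anchors every
raw sample to a reference coordinate:

* reference bases consumed by ``M``/``=``/``X`` keep their read base's samples
  as MATCH ops;
* read-only bases (``I``) contribute their samples as SIG_INS ops, kept
  between the flanking MATCH ops so the renderer can stack them at the border
  of the preceding reference base;
* reference-only bases (``D``/``N``) become BASE_DEL ops, with ``N`` spans
  recorded separately so a renderer can draw intron skips differently;
* soft-clipped (``S``) samples are trimmed off the signal span rather than
  emitted.

Output ops run in read sequencing order (for − strand reads that is
*decreasing* reference coordinate); :func:`orient_for_reference` flips a −
strand alignment so op order runs with increasing reference coordinate, which
is what pileup layout consumes.
"""

from __future__ import annotations

from .formats_io import ReadRecord
from .ss_codec import OpKind, SsAlignment, SsOp, canonicalize, sample_slices


class RealignError(ValueError):
    pass


def realign(sig2read: SsAlignment, read: ReadRecord) -> SsAlignment:
    """Compose a signal-to-read alignment with the read's reference CIGAR."""
    if sig2read.seq_kind != "read":
        raise RealignError("realign needs a signal-to-read alignment (seq_kind='read')")
    if read.ref_name is None or not read.cigar:
        raise RealignError(f"read {read.read_id} is unaligned; cannot realign")
    cig = read.cigar_ops()
    if any(op == "H" for op, _ in cig):
        raise RealignError(f"read {read.read_id}: hard-clipped alignment but signal "
                           "covers the full read; re-align without hard clipping")
    qlen = sum(n for op, n in cig if op in "MIS=X")
    if read.sequence and qlen != len(read.sequence):
        raise RealignError(f"read {read.read_id}: CIGAR query span {qlen} != "
                           f"sequence length {len(read.sequence)}")
    if (sig2read.seq_start, sig2read.seq_end) != (0, qlen):
        raise RealignError(f"read {read.read_id}: signal-to-read alignment covers "
                           f"[{sig2read.seq_start},{sig2read.seq_end}) of a {qlen}-base read")

    # Per-base sample slices in sequencing order, plus insertion samples
    # attached to the gap before a given base index.
    slices = sample_slices(sig2read)
    dwell: list[tuple[int, int] | None] = []
    ins_before: dict[int, list[tuple[int, int]]] = {}
    base_idx = sig2read.seq_start
    for op, sl in zip(sig2read.ops, slices):
        if op.kind is OpKind.MATCH:
            dwell.append(sl)
            base_idx += 1
        elif op.kind is OpKind.BASE_DEL:
            dwell.extend([None] * op.length)
            base_idx += op.length
        else:  # SIG_INS
            ins_before.setdefault(base_idx, []).append(sl)

    minus = read.strand == "-"

    def seq_index(q: int) -> int:
        return qlen - 1 - q if minus else q

    out_ops: list[SsOp] = []
    kept: list[tuple[int, int]] = []
    skip_refs: list[tuple[int, int]] = []

    def emit_ins_for(i_gap: int) -> None:
        for sl in ins_before.pop(i_gap, ()):  # samples aligned to no base
            out_ops.append(SsOp(OpKind.SIG_INS, sl[1] - sl[0]))
            kept.append(sl)

    q = 0
    r = read.ref_start
    for op, n in cig:
        if op in "M=X":
            for _ in range(n):
                i = seq_index(q)
                if not minus:
                    emit_ins_for(i)
                sl = dwell[i]
                if sl is None:
                    out_ops.append(SsOp(OpKind.BASE_DEL, 1))
                else:
                    out_ops.append(SsOp(OpKind.MATCH, sl[1] - sl[0]))
                    kept.append(sl)
                if minus:
                    emit_ins_for(i)
                q += 1
                r += 1
        elif op == "I":
            for _ in range(n):
                i = seq_index(q)
                if not minus:
                    emit_ins_for(i)
                sl = dwell[i]
                if sl is not None:
                    out_ops.append(SsOp(OpKind.SIG_INS, sl[1] - sl[0]))
                    kept.append(sl)
                if minus:
                    emit_ins_for(i)
                q += 1
        elif op == "S":
            q += n  # clipped samples fall off the signal span
        elif op in "DN":
            if op == "N":
                skip_refs.append((r, r + n))
            out_ops.append(SsOp(OpKind.BASE_DEL, n))
            r += n

    if not kept:
        raise RealignError(f"read {read.read_id}: no aligned signal left after clipping")

    ops = canonicalize(out_ops)
    if minus:
        ops = ops[::-1]  # sequencing order: decreasing reference coordinate
    return SsAlignment(
        read_id=read.read_id,
        ops=ops,
        sig_start=min(s for s, _ in kept),
        sig_end=max(e for _, e in kept),
        seq_start=read.ref_start,
        seq_end=r,
        seq_kind="reference",
        strand=read.strand,
        signal_direction=sig2read.signal_direction,
        ref_name=read.ref_name,
    )


def orient_for_reference(sig2ref: SsAlignment, strand: str | None = None) -> SsAlignment:
    """Flip a − strand alignment so op order runs with increasing reference coordinate.

    The op list is reversed and ``signal_direction`` flipped; + strand
    alignments pass through unchanged.  The operation is an involution.
    """
    if sig2ref.seq_kind != "reference":
        raise RealignError("orient_for_reference needs a signal-to-reference alignment")
    strand = strand or sig2ref.strand
    if strand == "+":
        return sig2ref
    flipped = "reverse" if sig2ref.signal_direction == "forward" else "forward"
    return sig2ref.replaced(ops=sig2ref.ops[::-1], signal_direction=flipped)


def is_oriented(sig2ref: SsAlignment) -> bool:
    """True when op order runs with increasing reference coordinate.

    + strand alignments always are.  For DNA − strand alignments the op order
    convention is carried by ``signal_direction``: realign emits sequencing
    order (``forward``), orientation flips it (``reverse``).
    """
    return sig2ref.strand == "+" or sig2ref.signal_direction == "reverse"


def ensure_oriented(sig2ref: SsAlignment) -> SsAlignment:
    """Orient to increasing reference coordinate if not already."""
    return sig2ref if is_oriented(sig2ref) else orient_for_reference(sig2ref)
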