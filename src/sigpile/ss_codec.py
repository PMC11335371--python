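"""The ``ss`` tag: a CIGAR-like encoding of signal-to-sequence alignments.

A nanopore read is a time series of current samples ("squiggle").  A
signal-to-sequence alignment anchors runs of consecutive samples to bases of
either the basecalled read or a reference sequence.  The alignment is carried
on SAM/PAF records as two auxiliary tags:

``ss:Z:``
    An ordered list of operations, one glyph per op:

    ========  =======  ==================================================
    glyph     op       meaning
    ========  =======  ==================================================
    ``n,``    MATCH    *n* signal samples aligned to exactly one base
    ``nI``    SIG_INS  *n* signal samples aligned to no base
    ``mD``    BASE_DEL *m* bases with no signal
    ========  =======  ==================================================

    e.g. ``"8,5I4,2D6,"`` reads: 8 samples on one base, 5 inserted samples,
    4 samples on the next base, 2 bases without signal, 6 samples on the
    following base.

``si:Z:``
    The coordinates of the aligned spans as four decimal integers
    ``sig_start,sig_end,seq_start,seq_end`` (0-based, half-open).

Canonical form forbids two adjacent ``SIG_INS`` or two adjacent ``BASE_DEL``
ops (they must be merged); adjacent ``MATCH`` ops are the normal encoding of
consecutive bases, since each MATCH op binds exactly one base.

Two conservation laws tie an alignment together and are enforced by
:func:`validate`:

* signal: ``sum(MATCH) + sum(SIG_INS) == sig_end - sig_start``
* sequence: ``count(MATCH) + sum(BASE_DEL) == seq_end - seq_start``
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


class SsError(ValueError):
    """Raised on malformed ss/si text or invariant violations."""


class OpKind(enum.Enum):
    MATCH = ","
    SIG_INS = "I"
    BASE_DEL = "D"


@dataclass(frozen=True)
class SsOp:
    """One alignment operation. ``length`` is samples (MATCH, SIG_INS) or bases (BASE_DEL)."""

    kind: OpKind
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SsError(f"op length must be >= 1, got {self.length}")


def match(n: int) -> SsOp:
    return SsOp(OpKind.MATCH, n)


def sig_ins(n: int) -> SsOp:
    return SsOp(OpKind.SIG_INS, n)


def base_del(n: int) -> SsOp:
    return SsOp(OpKind.BASE_DEL, n)


@dataclass
class SsAlignment:
    """One read's signal-to-sequence alignment.

    ``seq_kind`` records whether the sequence axis is the basecalled read or a
    reference.  ``signal_direction`` records whether op order runs with
    (``forward``) or against (``reverse``) raw sample acquisition order; it is
    ``reverse`` after a − strand alignment is oriented to increasing reference
    coordinate, and for direct-RNA reads whose sequence is stored 5'→3' while
    acquisition ran 3'→5'.
    """

    read_id: str
    ops: tuple[SsOp, ...]
    sig_start: int
    sig_end: int
    seq_start: int
    seq_end: int
    seq_kind: str = "read"  # "read" | "reference"
    strand: str = "+"
    signal_direction: str = "forward"  # "forward" | "reverse"
    ref_name: str | None = None

    def __post_init__(self) -> None:
        self.ops = tuple(self.ops)
        if self.seq_kind not in ("read", "reference"):
            raise SsError(f"bad seq_kind {self.seq_kind!r}")
        if self.strand not in "+-":
            raise SsError(f"bad strand {self.strand!r}")
        if self.signal_direction not in ("forward", "reverse"):
            raise SsError(f"bad signal_direction {self.signal_direction!r}")

    # -- derived quantities -------------------------------------------------
    @property
    def n_match(self) -> int:
        return sum(1 for op in self.ops if op.kind is OpKind.MATCH)

    @property
    def signal_samples(self) -> int:
        """Samples consumed by the op list (MATCH + SIG_INS)."""
        return sum(op.length for op in self.ops if op.kind is not OpKind.BASE_DEL)

    @property
    def seq_bases(self) -> int:
        """Bases consumed by the op list (one per MATCH, plus BASE_DEL runs)."""
        return sum(1 if op.kind is OpKind.MATCH else op.length
                   for op in self.ops if op.kind is not OpKind.SIG_INS)

    def replaced(self, **kw) -> "SsAlignment":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# emit / parse
# ---------------------------------------------------------------------------

def canonicalize(ops: Iterable[SsOp]) -> tuple[SsOp, ...]:
    """Merge adjacent SIG_INS runs and adjacent BASE_DEL runs.

    Adjacent MATCH ops are left alone: each binds its own base.
    """
    out: list[SsOp] = []
    for op in ops:
        if (out and op.kind is not OpKind.MATCH and out[-1].kind is op.kind):
            out[-1] = SsOp(op.kind, out[-1].length + op.length)
        else:
            out.append(op)
    return tuple(out)


def _check_canonical(ops: Sequence[SsOp]) -> str | None:
    for a, b in zip(ops, ops[1:]):
        if a.kind is b.kind and a.kind is not OpKind.MATCH:
            return f"adjacent {a.kind.name} ops (canonical form violation)"
    return None


def emit_ss(alignment: SsAlignment | Sequence[SsOp]) -> str:
    """Serialize an op list to ss-string text.

    When given a full :class:`SsAlignment`, its conservation invariants are
    checked first and violations raise :class:`SsError`.
    """
    if isinstance(alignment, SsAlignment):
        msg = _check_canonical(alignment.ops)
        if msg:
            raise SsError(msg)
        if alignment.signal_samples != alignment.sig_end - alignment.sig_start:
            raise SsError("signal conservation violated: op samples "
                          f"{alignment.signal_samples} != signal span "
                          f"{alignment.sig_end - alignment.sig_start}")
        if alignment.seq_bases != alignment.seq_end - alignment.seq_start:
            raise SsError("sequence conservation violated: op bases "
                          f"{alignment.seq_bases} != sequence span "
                          f"{alignment.seq_end - alignment.seq_start}")
        ops: Sequence[SsOp] = alignment.ops
    else:
        ops = tuple(alignment)
        msg = _check_canonical(ops)
        if msg:
            raise SsError(msg)
    return "".join(f"{op.length}{op.kind.value}" for op in ops)


_TOKEN = re.compile(r"(\d+)([,ID])")


def parse_ss(text: str) -> list[SsOp]:
    """Parse ss-string text into an op list.

    Inverse of :func:`emit_ss`; raises :class:`SsError` with the byte offset
    of the first offending character on malformed input.
    """
    ops: list[SsOp] = []
    pos = 0
    n = len(text)
    while pos < n:
        m = _TOKEN.match(text, pos)
        if m is None:
            raise SsError(f"malformed ss string at byte {pos}: {text[pos:pos + 10]!r}")
        length = int(m.group(1))
        if length == 0:
            raise SsError(f"zero-length op at byte {pos}")
        kind = OpKind(m.group(2))
        ops.append(SsOp(kind, length))
        pos = m.end()
    return ops


# ---------------------------------------------------------------------------
# si coordinate tag
# ---------------------------------------------------------------------------

def emit_si(alignment: SsAlignment) -> str:
    """Serialize the four span coordinates: ``sig_start,sig_end,seq_start,seq_end``."""
    a = alignment
    if a.sig_end < a.sig_start or a.seq_end < a.seq_start:
        raise SsError("si spans must be non-negative (end >= start)")
    if min(a.sig_start, a.seq_start) < 0:
        raise SsError("si coordinates must be non-negative")
    return f"{a.sig_start},{a.sig_end},{a.seq_start},{a.seq_end}"


def parse_si(text: str) -> tuple[int, int, int, int]:
    """Parse an si tag back into ``(sig_start, sig_end, seq_start, seq_end)``."""
    parts = text.split(",")
    if len(parts) != 4:
        raise SsError(f"si tag needs 4 comma-separated integers, got {text!r}")
    try:
        sig_start, sig_end, seq_start, seq_end = (int(p) for p in parts)
    except ValueError as e:
        raise SsError(f"non-integer si field in {text!r}") from e
    if sig_end < sig_start or seq_end < seq_start:
        raise SsError(f"si spans inverted in {text!r}")
    return sig_start, sig_end, seq_start, seq_end


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(alignment: SsAlignment, signal_len: int, seq_len: int) -> list[str]:
    """Check conservation invariants and coordinate bounds.

    Returns a list of human-readable violations; empty iff the alignment is
    internally consistent and fits inside ``[0, signal_len]`` / ``[0, seq_len]``.
    """
    a = alignment
    out: list[str] = []
    sig_span = a.sig_end - a.sig_start
    seq_span = a.seq_end - a.seq_start
    if a.signal_samples != sig_span:
        out.append("signal conservation: MATCH+SIG_INS samples "
                   f"{a.signal_samples} != sig span {sig_span}")
    if a.seq_bases != seq_span:
        out.append("sequence conservation: MATCH count + BASE_DEL bases "
                   f"{a.seq_bases} != seq span {seq_span}")
    if not (0 <= a.sig_start <= a.sig_end <= signal_len):
        out.append(f"signal span [{a.sig_start},{a.sig_end}) outside [0,{signal_len}]")
    if not (0 <= a.seq_start <= a.seq_end <= seq_len):
        out.append(f"sequence span [{a.seq_start},{a.seq_end}) outside [0,{seq_len}]")
    msg = _check_canonical(a.ops)
    if msg:
        out.append(msg)
    return out


# ---------------------------------------------------------------------------
# sample bookkeeping shared by realign / shift correction / layout
# ---------------------------------------------------------------------------

def sample_slices(alignment: SsAlignment) -> list[tuple[int, int] | None]:
    """Absolute sample interval for each op, in op order.

    MATCH and SIG_INS ops get a half-open ``(start, end)`` interval into the
    raw sample array; BASE_DEL ops get ``None``.  When ``signal_direction`` is
    ``reverse`` the first op's samples sit at the *end* of the signal span, so
    the walk runs downward from ``sig_end``.
    """
    out: list[tuple[int, int] | None] = []
    if alignment.signal_direction == "forward":
        cur = alignment.sig_start
        for op in alignment.ops:
            if op.kind is OpKind.BASE_DEL:
                out.append(None)
            else:
                out.append((cur, cur + op.length))
                cur += op.length
    else:
        cur = alignment.sig_end
        for op in alignment.ops:
            if op.kind is OpKind.BASE_DEL:
                out.append(None)
            else:
                out.append((cur - op.length, cur))
                cur -= op.length
    return out
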