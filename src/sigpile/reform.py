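"""Convert basecaller move tables into signal-to-read alignments.

During basecalling the neural network emits one output per *stride* raw
samples; the move table flags the strides at which a new base of the
basecalled sequence begins.  Together with the number of leading samples
trimmed before basecalling (adapter/stall signal), this pins every base to a
contiguous run of raw samples.  ``reform`` re-expresses that mapping as an
:class:`~sigpile.ss_codec.SsAlignment` carried on the read via ``ss``/``si``
tags.

Move tables map every base to at least one stride of signal, so reform never
emits SIG_INS or BASE_DEL ops.  Raw samples beyond the last stride slot
(``trim + stride * len(moves)`` onward) are unmodeled by the basecaller and
are excluded from the alignment rather than attributed to the last base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .formats_io import RawSignal, ReadRecord, FormatError
from .ss_codec import OpKind, SsAlignment, SsOp


class MoveTableError(ValueError):
    pass


@dataclass
class MoveTable:
    """Basecaller stride, per-stride move flags, and leading trim for one read."""

    stride: int
    moves: np.ndarray          # 0/1 per stride slot; moves[0] == 1
    trim_samples: int = 0

    def __post_init__(self) -> None:
        self.moves = np.asarray(self.moves, dtype=np.int8)
        if self.stride < 1:
            raise MoveTableError(f"stride must be positive, got {self.stride}")
        if self.trim_samples < 0:
            raise MoveTableError(f"trim_samples must be >= 0, got {self.trim_samples}")
        if self.moves.size == 0:
            raise MoveTableError("empty move table")
        if self.moves[0] != 1:
            raise MoveTableError("move table must start with 1 (first base at first slot)")
        if not np.isin(self.moves, (0, 1)).all():
            raise MoveTableError("move flags must be 0 or 1")

    @property
    def n_bases(self) -> int:
        return int(self.moves.sum())

    @classmethod
    def from_read(cls, read: ReadRecord) -> "MoveTable":
        """Build from the ``mv:B:c`` (stride-prefixed move vector) and ``ts:i`` tags."""
        if "mv" not in read.tags:
            raise MoveTableError(f"read {read.read_id} has no mv tag")
        mv = list(read.tags["mv"][0])
        if len(mv) < 2:
            raise MoveTableError(f"read {read.read_id}: mv tag too short")
        trim = int(read.tags["ts"][0]) if "ts" in read.tags else 0
        return cls(stride=int(mv[0]), moves=np.array(mv[1:]), trim_samples=trim)

    @classmethod
    def from_tsv(cls, path: str | Path) -> dict[str, "MoveTable"]:
        """Fixture loader: TSV of ``read_id  stride  trim  moves`` (moves comma-separated)."""
        out: dict[str, MoveTable] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) != 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 fields")
                out[f[0]] = cls(stride=int(f[1]), trim_samples=int(f[2]),
                                moves=np.fromstring(f[3], dtype=np.int8, sep=","))
        return out

    def to_tag(self) -> list[int]:
        return [int(self.stride)] + [int(v) for v in self.moves]


def moves_to_intervals(mt: MoveTable) -> np.ndarray:
    """Per-base half-open sample intervals, shape (n_bases, 2).

    Base *i* spans ``[trim + stride*slot_i, trim + stride*slot_{i+1})`` where
    ``slot_i`` is the position of the i-th move flag; the last base ends at
    ``trim + stride*len(moves)``.  Intervals tile the modeled signal span
    exactly and each is at least one stride long.
    """
    slots = np.flatnonzero(mt.moves)
    starts = mt.trim_samples + mt.stride * slots
    ends = np.empty_like(starts)
    ends[:-1] = starts[1:]
    ends[-1] = mt.trim_samples + mt.stride * len(mt.moves)
    return np.column_stack([starts, ends])


def reform(mt: MoveTable, read: ReadRecord,
           signal: RawSignal | None = None, rna: bool = False) -> SsAlignment:
    """Build the signal-to-read alignment for one read.

    Emits one MATCH op per basecalled base whose length is the base's sample
    interval.  ``rna=True`` marks ``signal_direction='reverse'``: direct-RNA
    sequences are stored 5'→3' while the molecule translocated 3'→5', so op
    order runs against acquisition order.
    """
    if read.sequence and mt.n_bases != len(read.sequence):
        raise MoveTableError(
            f"read {read.read_id}: move table encodes {mt.n_bases} bases but "
            f"sequence has {len(read.sequence)}")
    intervals = moves_to_intervals(mt)
    if signal is not None and intervals[-1, 1] > len(signal):
        raise MoveTableError(
            f"read {read.read_id}: move table spans {intervals[-1, 1]} samples "
            f"but signal has {len(signal)}")
    ops = tuple(SsOp(OpKind.MATCH, int(e - s)) for s, e in intervals)
    if rna:
        # 5'->3' base order walks the signal from its end
        ops = ops[::-1]
    return SsAlignment(
        read_id=read.read_id,
        ops=ops,
        sig_start=int(intervals[0, 0]),
        sig_end=int(intervals[-1, 1]),
        seq_start=0,
        seq_end=int(mt.n_bases),
        seq_kind="read",
        strand=read.strand,
        signal_direction="reverse" if rna else "forward",
    )
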