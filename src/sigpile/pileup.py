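"""Pileup geometry: screen-space layout of aligned signal over a region.

Two horizontal layouts exist for a single read:

* **time-scale** — consecutive samples are spaced uniformly, so base columns
  are as wide as their dwell;
* **molecule-scale** — samples are dynamically re-packed so every base column
  has identical width (``base_width``), which is what makes multi-read
  pileups line up despite variable translocation speed.

A pileup over a reference region stacks reads into per-strand tracks
(− strand reads first oriented so their columns coincide with + columns),
overlays every selected read in a shared track, and appends annotation and
simulated-data tracks.  Deleted bases leave labelled gaps; inserted samples
collapse onto a marker at the border of the preceding reference base.

The layout is pure geometry: rendering to HTML/SVG lives in
:mod:`sigpile.render`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .formats_io import AnnotationTrack, RawSignal, Region
from .realign import ensure_oriented
from .ss_codec import OpKind, SsAlignment, sample_slices


class LayoutError(ValueError):
    pass


@dataclass
class ReadGlyph:
    """Resolved geometry for one read: a polyline plus gap/insertion marks."""

    read_id: str
    strand: str
    polyline: list[tuple[float, float]]          # (x, pA)
    columns: list[tuple[float, float, str]]      # per-base (x0, x1, base)
    gap_spans: list[tuple[float, float, str]]    # deleted bases (x0, x1, labels)
    insertion_markers: list[tuple[float, list[float]]]  # (x, sample pA values)

    @property
    def n_samples(self) -> int:
        return len(self.polyline) + sum(len(v) for _, v in self.insertion_markers)


@dataclass
class Track:
    kind: str                    # pileup_overlay | stacked_reads | annotation | simulated
    strand: str = "both"         # + | - | both
    members: list[str] = field(default_factory=list)
    rows: dict[str, int] = field(default_factory=dict)  # read_id -> stacked row

    @property
    def n_rows(self) -> int:
        return max(self.rows.values()) + 1 if self.rows else 1


@dataclass
class PileupLayout:
    region: Region
    base_width: float
    tracks: list[Track]
    columns: list[tuple[float, float, str]]      # reference base columns
    glyphs: dict[str, ReadGlyph] = field(default_factory=dict)
    sim_glyphs: dict[str, ReadGlyph] = field(default_factory=dict)
    annotations: list[tuple[float, float, str, str | None]] = field(default_factory=list)

    @property
    def width(self) -> float:
        return len(self.region) * self.base_width


@dataclass
class PileupOptions:
    base_width: float = 24.0
    selected_reads: list[str] | None = None      # None = all selected
    annotations: AnnotationTrack | None = None
    simulated: list[tuple[SsAlignment, RawSignal]] | None = None
    max_reads: int | None = None


# ---------------------------------------------------------------------------
# single-read layouts
# ---------------------------------------------------------------------------

def _op_values(pA: np.ndarray, sl: tuple[int, int], direction: str) -> np.ndarray:
    vals = pA[sl[0]:sl[1]]
    # reverse-direction ops store acquisition order; flip so values read
    # left-to-right along the sequence axis
    return vals[::-1] if direction == "reverse" else vals


def layout_time_scale(aln: SsAlignment, signal: RawSignal,
                      sequence: str | None = None, unit: float = 1.0) -> ReadGlyph:
    """Uniform sample spacing: x of the i-th plotted sample is ``i * unit``."""
    pA = signal.to_pA()
    slices = sample_slices(aln)
    seq_offset = 0 if aln.seq_kind == "read" else aln.seq_start
    polyline: list[tuple[float, float]] = []
    columns: list[tuple[float, float, str]] = []
    gaps: list[tuple[float, float, str]] = []
    x = 0.0
    pos = aln.seq_start
    for op, sl in zip(aln.ops, slices):
        if op.kind is OpKind.MATCH:
            vals = _op_values(pA, sl, aln.signal_direction)
            x0 = x
            for v in vals:
                polyline.append((x, float(v)))
                x += unit
            base = sequence[pos - seq_offset] if sequence else "N"
            columns.append((x0, x, base))
            pos += 1
        elif op.kind is OpKind.SIG_INS:
            for v in _op_values(pA, sl, aln.signal_direction):
                polyline.append((x, float(v)))
                x += unit
        else:  # BASE_DEL: zero width in time, label the missing bases
            labels = (sequence[pos - seq_offset:pos - seq_offset + op.length]
                      if sequence else "?" * op.length)
            gaps.append((x, x, labels))
            pos += op.length
    return ReadGlyph(aln.read_id, aln.strand, polyline, columns, gaps, [])


def layout_molecule_scale(aln: SsAlignment, signal: RawSignal,
                          sequence: str | None = None,
                          base_width: float = 24.0,
                          origin: int | None = None) -> ReadGlyph:
    """Equal-width base columns; a base's n samples sit at
    ``left + base_width * (j + 0.5) / n``.

    ``origin`` fixes the sequence position mapped to x=0 (defaults to the
    alignment's own start, so a pileup passes the region start to make all
    glyphs share one coordinate frame).
    """
    aln = ensure_oriented(aln) if aln.seq_kind == "reference" else aln
    if origin is None:
        origin = aln.seq_start
    pA = signal.to_pA()
    slices = sample_slices(aln)
    seq_offset = 0 if aln.seq_kind == "read" else 0
    polyline: list[tuple[float, float]] = []
    columns: list[tuple[float, float, str]] = []
    gaps: list[tuple[float, float, str]] = []
    markers: list[tuple[float, list[float]]] = []
    pos = aln.seq_start

    def col_left(p: int) -> float:
        return (p - origin) * base_width

    for op, sl in zip(aln.ops, slices):
        if op.kind is OpKind.MATCH:
            left = col_left(pos)
            vals = _op_values(pA, sl, aln.signal_direction)
            n = len(vals)
            for j, v in enumerate(vals):
                polyline.append((left + base_width * (j + 0.5) / n, float(v)))
            base = sequence[pos - aln.seq_start] if sequence else "N"
            columns.append((left, left + base_width, base))
            pos += 1
        elif op.kind is OpKind.SIG_INS:
            vals = _op_values(pA, sl, aln.signal_direction)
            # stacked at the border of the preceding base column
            markers.append((col_left(pos), [float(v) for v in vals]))
        else:  # BASE_DEL
            labels = (sequence[pos - aln.seq_start:pos - aln.seq_start + op.length]
                      if sequence else "?" * op.length)
            gaps.append((col_left(pos), col_left(pos + op.length), labels))
            pos += op.length
    return ReadGlyph(aln.read_id, aln.strand, polyline, columns, gaps, markers)


# ---------------------------------------------------------------------------
# region clipping
# ---------------------------------------------------------------------------

def clip_to_region(aln: SsAlignment, region: Region) -> SsAlignment | None:
    """Restrict an oriented signal-to-reference alignment to a region.

    Whole base columns are kept or dropped; clipped samples leave the signal
    span.  Returns None when no MATCH op survives.
    """
    aln = ensure_oriented(aln)
    slices = sample_slices(aln)
    # kept: (op, slice-or-None, unit start position or None for SIG_INS)
    kept: list[tuple] = []
    pos = aln.seq_start
    for op, sl in zip(aln.ops, slices):
        if op.kind is OpKind.MATCH:
            if region.start <= pos < region.end:
                kept.append((op, sl, pos))
            pos += 1
        elif op.kind is OpKind.BASE_DEL:
            lo = max(pos, region.start)
            hi = min(pos + op.length, region.end)
            if hi > lo:
                kept.append((op.__class__(op.kind, hi - lo), None, lo))
            pos += op.length
        else:  # SIG_INS rides with its neighbourhood
            if region.start < pos < region.end:
                kept.append((op, sl, None))
    if not any(op.kind is OpKind.MATCH for op, _, _ in kept):
        return None
    # trim leading/trailing BASE_DEL (and any insertion outside them)
    while kept and kept[0][0].kind is not OpKind.MATCH:
        kept.pop(0)
    while kept and kept[-1][0].kind is not OpKind.MATCH:
        kept.pop()
    seq_start = kept[0][2]
    seq_end = kept[-1][2] + 1
    kept_slices = [sl for _, sl, _ in kept if sl is not None]
    sig_start = min(s for s, _ in kept_slices)
    sig_end = max(e for _, e in kept_slices)
    return aln.replaced(ops=tuple(op for op, _, _ in kept),
                        seq_start=seq_start, seq_end=seq_end,
                        sig_start=sig_start, sig_end=sig_end)


# ---------------------------------------------------------------------------
# pileup assembly
# ---------------------------------------------------------------------------

def _pack_rows(extents: list[tuple[str, float, float]]) -> dict[str, int]:
    """First-fit interval packing so stacked rows never overlap."""
    rows: list[float] = []  # rightmost x per row
    out: dict[str, int] = {}
    for read_id, x0, x1 in sorted(extents, key=lambda e: (e[1], e[2], e[0])):
        for ri, right in enumerate(rows):
            if x0 >= right:
                rows[ri] = x1
                out[read_id] = ri
                break
        else:
            rows.append(x1)
            out[read_id] = len(rows) - 1
    return out


def build_pileup(region: Region,
                 alignments: list[SsAlignment],
                 signals: dict[str, RawSignal],
                 reference: str,
                 options: PileupOptions | None = None) -> PileupLayout:
    """Assemble the full pileup layout for a region.

    Track order: annotation, simulated, + overlay, + stack, − overlay,
    − stack.  The overlay tracks contain every *selected* read's polyline;
    stacks always contain every overlapping read.
    """
    options = options or PileupOptions()
    bw = options.base_width
    refseq = reference[region.start:region.end]
    columns = [((i * bw), ((i + 1) * bw), refseq[i]) for i in range(len(refseq))]
    layout = PileupLayout(region=region, base_width=bw, tracks=[], columns=columns)

    overlapping = [a for a in alignments
                   if a.seq_kind == "reference"
                   and (a.ref_name is None or a.ref_name == region.ref_name)
                   and a.seq_start < region.end and a.seq_end > region.start]
    if options.max_reads is not None:
        overlapping = overlapping[:options.max_reads]
    if not overlapping:
        warnings.warn(f"no reads overlap {region.ref_name}:{region.start}-{region.end}")

    if options.annotations is not None:
        ann = [( (iv.start - region.start) * bw, (iv.end - region.start) * bw,
                 label, color)
               for iv, label, color in options.annotations.in_region(region)]
        layout.annotations = ann
        layout.tracks.append(Track(kind="annotation"))

    if options.simulated:
        members = []
        for aln, sig in options.simulated:
            clipped = clip_to_region(aln, region)
            if clipped is None:
                continue
            seq = reference[clipped.seq_start:clipped.seq_end]
            g = layout_molecule_scale(clipped, sig, seq, bw, origin=region.start)
            layout.sim_glyphs[g.read_id] = g
            members.append(g.read_id)
        layout.tracks.append(Track(kind="simulated", members=members))

    for strand in "+-":
        members: list[str] = []
        extents: list[tuple[str, float, float]] = []
        for aln in overlapping:
            if aln.strand != strand:
                continue
            clipped = clip_to_region(aln, region)
            if clipped is None:
                continue
            seq = reference[clipped.seq_start:clipped.seq_end]
            glyph = layout_molecule_scale(clipped, signals[aln.read_id], seq,
                                          bw, origin=region.start)
            layout.glyphs[glyph.read_id] = glyph
            members.append(glyph.read_id)
            x0 = (clipped.seq_start - region.start) * bw
            x1 = (clipped.seq_end - region.start) * bw
            extents.append((glyph.read_id, x0, x1))
        selected = [m for m in members
                    if options.selected_reads is None or m in options.selected_reads]
        layout.tracks.append(Track(kind="pileup_overlay", strand=strand,
                                   members=selected))
        layout.tracks.append(Track(kind="stacked_reads", strand=strand,
                                   members=members, rows=_pack_rows(extents)))
    return layout
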