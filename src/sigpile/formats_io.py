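"""File formats and domain containers.

The toolkit touches six external formats:

* FASTA references (indexed via :mod:`pyfaidx`).
* SAM (plain text, via :mod:`pysam`) and PAF for read alignments; signal
  alignments ride along as ``ss:Z:`` / ``si:Z:`` auxiliary tags, move tables
  as ``mv:B:c`` (stride-prefixed) and ``ts:i`` (trim).
* BED3+ annotation intervals.
* Pore models: TSV with columns ``kmer  level_mean  level_stdv``.
* A plain-text signal container (one line per read; see
  :func:`write_signal_container`) standing in for binary squiggle archives —
  the requirement it serves is keyed random access to per-read samples plus
  calibration, not a specific encoding.  A reader for another container can
  be dropped in by returning the same ``{read_id: RawSignal}`` mapping.

All coordinates are 0-based half-open internally; SAM's 1-based POS is
converted at the boundary in both directions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
import pyfaidx

from . import __version__
from .ss_codec import SsAlignment, SsError, emit_si, emit_ss, parse_si, parse_ss

CIGAR_OPS = "MIDNSHP=X"
_QUERY_CONSUMING = set("MIS=X")
_REF_CONSUMING = set("MDN=X")


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RawSignal:
    """Raw current samples for one read, plus calibration to pico-amps.

    ``samples`` are DAC units as recorded by the device (integers on real
    instruments; the container also accepts floats, which the simulator uses
    under an identity calibration).  Conversion:

        pA = (raw + offset_pA) * range_pA / digitisation
    """

    read_id: str
    samples: np.ndarray
    digitisation: float
    offset_pA: float
    range_pA: float
    sampling_rate: float = 4000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.digitisation <= 0 or self.range_pA <= 0 or self.sampling_rate <= 0:
            raise FormatError(f"read {self.read_id}: calibration constants must be positive")

    def to_pA(self) -> np.ndarray:
        return (self.samples + self.offset_pA) * (self.range_pA / self.digitisation)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class ReadRecord:
    """A basecalled read and (optionally) its alignment to a reference."""

    read_id: str
    sequence: str = ""
    ref_name: str | None = None
    ref_start: int = 0          # 0-based
    cigar: str = ""             # ops over M=XIDNSH
    strand: str = "+"
    mapq: int = 60
    tags: dict[str, tuple[object, str]] = field(default_factory=dict)
    # tags map tag name -> (value, SAM type letter)

    def cigar_ops(self) -> list[tuple[str, int]]:
        return parse_cigar(self.cigar)

    def query_span(self) -> int:
        return sum(n for op, n in self.cigar_ops() if op in _QUERY_CONSUMING)

    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar_ops() if op in _REF_CONSUMING)

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span()

    def get_tag(self, name: str):
        return self.tags[name][0]

    def set_tag(self, name: str, value, vtype: str = "Z") -> None:
        self.tags[name] = (value, vtype)


@dataclass(frozen=True)
class Region:
    """Half-open 0-based interval on a named sequence."""

    ref_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(f"bad region {self.ref_name}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, ref_name: str | None, start: int, end: int) -> bool:
        return ref_name == self.ref_name and start < self.end and end > self.start


def parse_region(text: str) -> Region:
    """Parse a browser-style region string ``name:start-end`` (1-based inclusive)."""
    m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text)
    if not m:
        raise FormatError(f"cannot parse region {text!r}; expected name:start-end")
    start = int(m.group(2).replace(",", "")) - 1
    end = int(m.group(3).replace(",", ""))
    return Region(m.group(1), start, end)


@dataclass
class AnnotationTrack:
    """Sorted BED-style intervals with labels, e.g. methylated CpG sites."""

    intervals: list[tuple[Region, str, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals.sort(key=lambda iv: (iv[0].ref_name, iv[0].start, iv[0].end))

    def in_region(self, region: Region) -> list[tuple[Region, str, str | None]]:
        return [iv for iv in self.intervals
                if region.overlaps(iv[0].ref_name, iv[0].start, iv[0].end)]


@dataclass
class PoreModel:
    """Expected current mean/sd per k-mer for one chemistry/protocol."""

    k: int
    levels: dict[str, tuple[float, float]]
    name: str = "unnamed"
    complete: bool = True

    def mean(self, kmer: str) -> float:
        return self.levels[kmer][0]

    def sd(self, kmer: str) -> float:
        return self.levels[kmer][1]

    def __len__(self) -> int:
        return len(self.levels)


# ---------------------------------------------------------------------------
# CIGAR helpers
# ---------------------------------------------------------------------------

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(text: str) -> list[tuple[str, int]]:
    if text in ("", "*"):
        return []
    ops: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _CIGAR_TOKEN.match(text, pos)
        if m is None or int(m.group(1)) == 0:
            raise FormatError(f"malformed CIGAR {text!r} at char {pos}")
        ops.append((m.group(2), int(m.group(1))))
        pos = m.end()
    return ops


# ---------------------------------------------------------------------------
# Signal container
# ---------------------------------------------------------------------------

_SIGNAL_MAGIC = "#sigpile-signal\tv1"
_SIGNAL_COLUMNS = "#read_id\tdigitisation\toffset_pA\trange_pA\tsampling_rate\tsamples"


def write_signal_container(path: str | Path, signals: Iterable[RawSignal]) -> None:
    """Write the plain-text signal container: one TSV line per read.

    Samples are comma-separated; integer arrays are written as integers so
    real DAC data round-trips byte-identically.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_SIGNAL_MAGIC + f"\t{_program_stamp()}\n")
        fh.write(_SIGNAL_COLUMNS + "\n")
        for sig in signals:
            if np.issubdtype(sig.samples.dtype, np.integer):
                sample_text = ",".join(str(int(v)) for v in sig.samples)
            else:
                sample_text = ",".join(repr(float(v)) for v in sig.samples)
            fh.write(f"{sig.read_id}\t{_num(sig.digitisation)}\t{_num(sig.offset_pA)}\t"
                     f"{_num(sig.range_pA)}\t{_num(sig.sampling_rate)}\t{sample_text}\n")


def read_signal_container(path: str | Path) -> dict[str, RawSignal]:
    """Load the container into a dict for O(1) lookup by read id."""
    path = Path(path)
    out: dict[str, RawSignal] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
            read_id = fields[0]
            if read_id in out:
                raise FormatError(f"{path}:{lineno}: duplicate read_id {read_id!r}")
            try:
                dig, off, rng, rate = (float(v) for v in fields[1:5])
            except ValueError as e:
                raise FormatError(
                    f"{path}:{lineno}: read {read_id!r} has a non-numeric "
                    f"calibration field") from e
            raw = fields[5]
            if raw == "":
                samples = np.array([], dtype=np.int64)
            elif "." in raw or "e" in raw or "E" in raw:
                samples = np.fromstring(raw, dtype=np.float64, sep=",")
            else:
                samples = np.fromstring(raw, dtype=np.int64, sep=",")
            out[read_id] = RawSignal(read_id, samples, dig, off, rng, rate)
    return out


def _num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _program_stamp() -> str:
    return f"sigpile-{__version__}"


# ---------------------------------------------------------------------------
# SAM / PAF
# ---------------------------------------------------------------------------

def _record_from_pysam(seg: pysam.AlignedSegment) -> ReadRecord:
    rec = ReadRecord(
        read_id=seg.query_name,
        sequence=seg.query_sequence or "",
        ref_name=None if seg.is_unmapped else seg.reference_name,
        ref_start=0 if seg.is_unmapped else seg.reference_start,
        cigar=seg.cigarstring or "",
        strand="-" if seg.is_reverse else "+",
        mapq=seg.mapping_quality,
    )
    for tag, value, vtype in seg.get_tags(with_value_type=True):
        if vtype == "B" and hasattr(value, "tolist"):
            value = list(value)
        rec.tags[tag] = (value, vtype)
    if rec.sequence and rec.cigar and rec.query_span() != len(rec.sequence):
        raise FormatError(
            f"read {rec.read_id}: CIGAR consumes {rec.query_span()} query bases "
            f"but sequence is {len(rec.sequence)} long")
    return rec


def read_alignments(path: str | Path, region: Region | None = None) -> list[ReadRecord]:
    """Read SAM (``.sam``) or PAF (``.paf``) alignments, optionally region-filtered.

    Region filtering is a linear scan with an exact overlap test; at desk
    scale (well under 10k records) this is already "in seconds".
    """
    path = Path(path)
    if path.suffix == ".paf":
        records = read_paf(path)
    else:
        records = []
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for seg in fh:
                records.append(_record_from_pysam(seg))
    if region is not None:
        records = [r for r in records
                   if r.ref_name is not None
                   and region.overlaps(r.ref_name, r.ref_start, r.ref_end)]
    return records


def write_alignments(path: str | Path, records: Sequence[ReadRecord],
                     ref_lengths: Mapping[str, int], sort: bool = True) -> None:
    """Write records as SAM (``.sam``) or PAF (``.paf``), coordinate-sorted."""
    path = Path(path)
    if sort:
        records = sorted(records, key=lambda r: (r.ref_name or "~", r.ref_start, r.read_id))
    if path.suffix == ".paf":
        write_paf(path, records, ref_lengths)
        return
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if sort else "unsorted"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in ref_lengths.items()],
        "PG": [{"ID": "sigpile", "PN": "sigpile", "VN": __version__}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = rec.read_id
            seg.query_sequence = rec.sequence or None
            flag = 0
            if rec.strand == "-":
                flag |= 16
            if rec.ref_name is None:
                flag |= 4
            seg.flag = flag
            if rec.ref_name is not None:
                seg.reference_name = rec.ref_name
                seg.reference_start = rec.ref_start
                seg.cigarstring = rec.cigar or None
                seg.mapping_quality = rec.mapq
            for tag, (value, vtype) in rec.tags.items():
                # pysam infers the element type of B (array) tags from the list
                seg.set_tag(tag, value, value_type=None if vtype == "B" else vtype)
            fh.write(seg)


_PAF_TAG_CASTS = {"i": int, "f": float, "A": str, "Z": str}


def read_paf(path: str | Path) -> list[ReadRecord]:
    records: list[ReadRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: PAF needs >= 12 columns")
            rec = ReadRecord(
                read_id=f[0],
                ref_name=None if f[5] == "*" else f[5],
                ref_start=int(f[7]),
                strand=f[4] if f[4] in "+-" else "+",
                mapq=int(f[11]),
            )
            for col in f[12:]:
                tag, vtype, value = col.split(":", 2)
                if vtype == "B":
                    letter, *vals = value.split(",")
                    cast = float if letter == "f" else int
                    rec.tags[tag] = ([cast(v) for v in vals], "B")
                else:
                    rec.tags[tag] = (_PAF_TAG_CASTS.get(vtype, str)(value), vtype)
            if "cg" in rec.tags:
                rec.cigar = str(rec.tags["cg"][0])
                parse_cigar(rec.cigar)  # malformed -> error
            records.append(rec)
    return records


def write_paf(path: str | Path, records: Sequence[ReadRecord],
              ref_lengths: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{_program_stamp()}\n")
        for rec in records:
            qlen = len(rec.sequence) if rec.sequence else rec.query_span()
            tname = rec.ref_name or "*"
            tlen = ref_lengths.get(rec.ref_name, 0) if rec.ref_name else 0
            ref_span = rec.ref_span()
            cols = [rec.read_id, str(qlen), "0", str(qlen), rec.strand,
                    tname, str(tlen), str(rec.ref_start), str(rec.ref_start + ref_span),
                    str(min(qlen, ref_span)), str(max(qlen, ref_span)), str(rec.mapq)]
            tags = dict(rec.tags)
            if rec.cigar and "cg" not in tags:
                tags["cg"] = (rec.cigar, "Z")
            for tag, (value, vtype) in tags.items():
                if vtype == "B":
                    letter = "f" if any(isinstance(v, float) for v in value) else "c"
                    cols.append(f"{tag}:B:{letter}," + ",".join(str(v) for v in value))
                else:
                    cols.append(f"{tag}:{vtype}:{value}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# ss/si tag <-> SsAlignment bridge
# ---------------------------------------------------------------------------

def attach_alignment(rec: ReadRecord, aln: SsAlignment) -> ReadRecord:
    """Store an ss alignment on a record as ss/si tags (plus sd for direction)."""
    rec.set_tag("ss", emit_ss(aln), "Z")
    rec.set_tag("si", emit_si(aln), "Z")
    rec.set_tag("sd", "r" if aln.signal_direction == "reverse" else "f", "A")
    return rec


def extract_alignment(rec: ReadRecord, seq_kind: str = "reference") -> SsAlignment:
    """Rebuild the ss alignment carried on a record's ss/si tags."""
    if "ss" not in rec.tags or "si" not in rec.tags:
        raise FormatError(f"read {rec.read_id} carries no ss/si tags")
    ops = parse_ss(str(rec.get_tag("ss")))
    sig_start, sig_end, seq_start, seq_end = parse_si(str(rec.get_tag("si")))
    sd = rec.tags.get("sd", ("f", "A"))[0]
    return SsAlignment(
        read_id=rec.read_id, ops=tuple(ops),
        sig_start=sig_start, sig_end=sig_end,
        seq_start=seq_start, seq_end=seq_end,
        seq_kind=seq_kind, strand=rec.strand,
        signal_direction="reverse" if sd == "r" else "forward",
        ref_name=rec.ref_name if seq_kind == "reference" else None,
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> AnnotationTrack:
    """Read BED3+ into a sorted annotation track."""
    intervals: list[tuple[Region, str, str | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            label = f[3] if len(f) > 3 else ""
            color = f[8] if len(f) > 8 else None
            intervals.append((Region(f[0], start, end), label, color))
    return AnnotationTrack(intervals)


# ---------------------------------------------------------------------------
# Pore model TSV
# ---------------------------------------------------------------------------

def read_pore_model(path: str | Path, name: str | None = None) -> PoreModel:
    """Read a ``kmer  level_mean  level_stdv`` TSV.

    A complete model has 4**k rows; missing k-mers produce a warning and an
    incomplete model, mixed k-mer lengths or duplicates are hard errors.
    """
    path = Path(path)
    levels: dict[str, tuple[float, float]] = {}
    k: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("kmer"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            kmer = f[0].upper()
            if k is None:
                k = len(kmer)
            elif len(kmer) != k:
                raise FormatError(f"{path}:{lineno}: mixed k-mer lengths ({len(kmer)} vs {k})")
            if kmer in levels:
                raise FormatError(f"{path}:{lineno}: duplicate k-mer {kmer}")
            levels[kmer] = (float(f[1]), float(f[2]))
    if k is None:
        raise FormatError(f"{path}: empty pore model")
    model = PoreModel(k=k, levels=levels, name=name or path.stem)
    if len(levels) < 4 ** k:
        warnings.warn(f"pore model {path} has {len(levels)}/{4 ** k} k-mers; "
                      "marked incomplete")
        model.complete = False
    return model


def write_pore_model(path: str | Path, model: PoreModel) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{_program_stamp()}\tmodel={model.name}\n")
        fh.write("kmer\tlevel_mean\tlevel_stdv\n")
        for kmer in sorted(model.levels):
            mean, sd = model.levels[kmer]
            fh.write(f"{kmer}\t{repr(float(mean))}\t{repr(float(sd))}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into memory; uses the pyfaidx index for random access."""
    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def fetch_fasta_region(path: str | Path, region: Region) -> str:
    fa = pyfaidx.Fasta(str(path))
    return str(fa[region.ref_name][region.start:region.end])
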