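"""Seeded nanopore signal simulator with ground-truth alignments.

The simulator emulates the standard pore-model picture of a nanopore squiggle
well enough to exercise every downstream component with known truth:

* per-base dwell times drawn from a truncated negative binomial (minimum one
  basecaller stride), reproducing the variable translocation speed that makes
  molecule-scale re-packing necessary;
* per-sample currents drawn ``Normal(model mean of the covering k-mer,
  model sd x noise multiplier)``, with k-mers anchored at their first base in
  read orientation — the move-table/eventalign convention — so the dataset
  carries a known k-mer-to-base shift equal to the model's MSB position;
* leading adapter samples (trimmed by ``ts``), trailing unmodeled samples,
  both strands, optional sequence variants and base modifications (a level
  offset at marked positions on a fraction of reads, the case-vs-control
  shape of methylation comparisons);
* move tables, perfect-CIGAR SAM records, and ground-truth signal-to-read and
  signal-to-reference ss alignments, all byte-reproducible from one seed.

It does not model amplitude drift, pore stalls, adapter waveforms, or the
error profile of a real basecaller beyond what :func:`inject_errors`
injects.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats_io import (
    PoreModel, RawSignal, ReadRecord, attach_alignment,
    write_alignments, write_fasta, write_pore_model, write_signal_container,
)
from .reform import MoveTable
from .shift_correction import COMPLEMENT
from .ss_codec import OpKind, SsAlignment, SsOp

BASES = "ACGT"
_BASE_VAL = {b: i for i, b in enumerate(BASES)}


class SimError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# synthetic pore model
# ---------------------------------------------------------------------------

def make_synthetic_model(k: int = 6, msb: int = 3, *,
                         msb_weight: float = 12.0,
                         minor_weight: float = 0.8,
                         level_noise_sd: float = 0.3,
                         level_sd: float = 1.5,
                         baseline: float = 85.0,
                         seed: int = 0,
                         name: str | None = None) -> PoreModel:
    """Generate a complete 4**k pore model with a designated MSB position.

    Level of a k-mer = baseline + msb_weight * v(base at msb)
    + minor_weight * sum of v(other bases) + Normal(0, level_noise_sd),
    with v(A,C,G,T) = 0,1,2,3.  With ``minor_weight=0`` and
    ``level_noise_sd=0`` the level is a pure function of the MSB base
    (eta-squared of exactly 1 at that position).
    """
    if not 0 <= msb < k:
        raise SimError(f"msb {msb} outside [0,{k})")
    rng = np.random.default_rng(seed)
    levels: dict[str, tuple[float, float]] = {}
    for idx in range(4 ** k):
        kmer = "".join(BASES[(idx >> (2 * (k - 1 - p))) & 3] for p in range(k))
        level = baseline + msb_weight * _BASE_VAL[kmer[msb]]
        level += minor_weight * sum(_BASE_VAL[kmer[p]] for p in range(k) if p != msb)
        if level_noise_sd > 0:
            level += rng.normal(0.0, level_noise_sd)
        levels[kmer] = (float(level), float(level_sd))
    return PoreModel(k=k, levels=levels,
                     name=name or f"synthetic-k{k}-msb{msb}")


def random_reference(length: int, seed: int = 0, name: str = "ref1") -> str:
    rng = np.random.default_rng(seed)
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class Modification:
    """A base modification: +delta_pA on the signal at ``ref_pos`` for a
    random ``fraction`` of reads (sequence unchanged)."""

    ref_pos: int
    delta_pA: float
    fraction: float = 0.5


@dataclass
class SimParams:
    depth: float = 20.0
    dwell_mean: float = 9.0          # samples per base, mean
    dwell_dispersion: float = 3.0    # negative-binomial dispersion (slots)
    noise_multiplier: float = 1.0    # scales model sd
    trim_samples: int = 20           # leading adapter samples
    strand_fraction: float = 0.5     # fraction of + strand reads
    stride: int = 5
    min_read_length: int = 100
    seed: int = 0
    rna: bool = False
    variants: list[tuple[int, str]] = field(default_factory=list)
    modifications: list[Modification] = field(default_factory=list)


@dataclass
class SimRead:
    record: ReadRecord
    signal: RawSignal
    move_table: MoveTable
    sig2read: SsAlignment
    sig2ref: SsAlignment
    is_modified: bool = False


@dataclass
class SimulatedDataset:
    reference: str
    ref_name: str
    model: PoreModel
    reads: list[SimRead]
    params: SimParams

    @property
    def signals(self) -> dict[str, RawSignal]:
        return {r.signal.read_id: r.signal for r in self.reads}

    @property
    def sig2ref_truth(self) -> list[SsAlignment]:
        return [r.sig2ref for r in self.reads]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the full bundle: FASTA, SAM (mv/ts tags), signal container,
        pore model, and ground-truth ss/si SAM files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ref": outdir / "ref.fa",
            "reads": outdir / "reads.sam",
            "signal": outdir / "signals.tsv",
            "model": outdir / "model.tsv",
            "sig2ref": outdir / "truth_sig2ref.sam",
            "sig2read": outdir / "truth_sig2read.sam",
        }
        write_fasta(paths["ref"], {self.ref_name: self.reference})
        write_signal_container(paths["signal"], [r.signal for r in self.reads])
        write_pore_model(paths["model"], self.model)
        ref_lengths = {self.ref_name: len(self.reference)}

        basecalled = [r.record for r in self.reads]
        write_alignments(paths["reads"], basecalled, ref_lengths)

        def tagged(rec: ReadRecord, aln: SsAlignment) -> ReadRecord:
            return attach_alignment(copy.deepcopy(rec), aln)

        write_alignments(paths["sig2ref"],
                         [tagged(r.record, r.sig2ref) for r in self.reads], ref_lengths)
        write_alignments(paths["sig2read"],
                         [tagged(r.record, r.sig2read) for r in self.reads], ref_lengths)
        return paths


def _dwell_slots(rng: np.random.Generator, n: int, mean_slots: float,
                 dispersion: float) -> np.ndarray:
    """Truncated negative binomial: 1 + NB with mean (mean_slots - 1)."""
    extra_mean = mean_slots - 1.0
    if extra_mean <= 0:
        return np.ones(n, dtype=np.int64)
    p = dispersion / (dispersion + extra_mean)
    return 1 + rng.negative_binomial(dispersion, p, size=n)


def simulate_dataset(reference: str | int, model: PoreModel,
                     params: SimParams | None = None) -> SimulatedDataset:
    """Simulate a fully seeded dataset over ``reference`` (a sequence, or a
    length to generate one from the same seed)."""
    params = params or SimParams()
    if params.depth <= 0:
        raise SimError(f"depth must be positive, got {params.depth}")
    if params.dwell_mean < 1:
        raise SimError(f"dwell mean must be >= 1 sample, got {params.dwell_mean}")
    rng = np.random.default_rng(params.seed)
    if isinstance(reference, int):
        reference = random_reference(reference, seed=params.seed)
    ref_name = "ref1"
    L = len(reference)
    molecule_ref = list(reference)
    for pos, alt in params.variants:
        molecule_ref[pos] = alt
    molecule_ref = "".join(molecule_ref)

    k = model.k
    mean_slots = params.dwell_mean / params.stride
    reads: list[SimRead] = []
    total_bases = 0
    target_bases = params.depth * L
    i = 0
    while total_bases < target_bases:
        read_len = int(rng.integers(min(params.min_read_length, L), L + 1))
        start = int(rng.integers(0, L - read_len + 1))
        end = start + read_len
        strand = "+" if (params.rna or rng.random() < params.strand_fraction) else "-"
        molecule = molecule_ref[start:end]
        read_seq = molecule if strand == "+" else revcomp(molecule)

        is_modified = bool(params.modifications) and bool(
            rng.random() < max(m.fraction for m in params.modifications))
        delta = np.zeros(read_len)
        if is_modified:
            for m in params.modifications:
                if start <= m.ref_pos < end:
                    r = (m.ref_pos - start) if strand == "+" else (end - 1 - m.ref_pos)
                    delta[r] += m.delta_pA

        padded = read_seq + "A" * k
        slots = _dwell_slots(rng, read_len, mean_slots, params.dwell_dispersion)
        dwells = slots * params.stride

        # acquisition order: read order for DNA, 3'->5' (reversed) for RNA
        order = np.arange(read_len) if not params.rna else np.arange(read_len)[::-1]
        chunks = []
        adapter = np.full(params.trim_samples, 80.0)
        if params.noise_multiplier > 0 and params.trim_samples:
            adapter = adapter + rng.normal(0, 5.0 * params.noise_multiplier,
                                           size=params.trim_samples)
        chunks.append(adapter)
        for r in order:
            kmer = padded[r:r + k]
            level = model.mean(kmer) + delta[r]
            sd = model.sd(kmer) * params.noise_multiplier
            if sd > 0:
                chunks.append(rng.normal(level, sd, size=int(dwells[r])))
            else:
                chunks.append(np.full(int(dwells[r]), level))
        trailing = int(rng.integers(0, 2 * params.stride))
        if trailing:
            chunks.append(np.full(trailing, 80.0))
        samples = np.concatenate(chunks)

        moves = np.zeros(int(slots.sum()), dtype=np.int8)
        moves[np.concatenate([[0], np.cumsum(slots[order])[:-1]])] = 1
        mt = MoveTable(stride=params.stride, moves=moves,
                       trim_samples=params.trim_samples)

        read_id = f"read{i:04d}"
        sig = RawSignal(read_id, samples,
                        digitisation=2048.0, offset_pA=0.0, range_pA=2048.0)
        rec = ReadRecord(read_id=read_id, sequence=read_seq, ref_name=ref_name,
                         ref_start=start, cigar=f"{read_len}M", strand=strand)
        rec.set_tag("mv", mt.to_tag(), "B")
        rec.set_tag("ts", params.trim_samples, "i")

        sig_start = params.trim_samples
        sig_end = sig_start + int(dwells.sum())
        direction = "reverse" if params.rna else "forward"
        match_ops = tuple(SsOp(OpKind.MATCH, int(d)) for d in dwells)
        sig2read = SsAlignment(read_id, match_ops, sig_start, sig_end,
                               0, read_len, "read", strand, direction)
        sig2ref = SsAlignment(read_id, match_ops, sig_start, sig_end,
                              start, end, "reference", strand, direction,
                              ref_name=ref_name)
        reads.append(SimRead(rec, sig, mt, sig2read, sig2ref, is_modified))
        total_bases += read_len
        i += 1
    return SimulatedDataset(reference, ref_name, model, reads, params)


# ---------------------------------------------------------------------------
# basecall / alignment error injection
# ---------------------------------------------------------------------------

def inject_errors(dataset: SimulatedDataset, *,
                  sub_rate: float = 0.0, ins_rate: float = 0.0,
                  del_rate: float = 0.0, max_softclip: int = 0,
                  seed: int = 0) -> SimulatedDataset:
    """Mutate basecalls and alignments: substitutions, hallucinated inserted
    bases (splitting an existing base's strides), missed bases (their strides
    merging into the previous base), and terminal soft clips.  Move tables,
    CIGARs and ground-truth ss alignments are re-derived consistently.
    """
    for name, rate in (("sub", sub_rate), ("ins", ins_rate), ("del", del_rate)):
        if not 0.0 <= rate <= 1.0:
            raise SimError(f"{name}_rate {rate} outside [0,1]")
    if dataset.params.rna and (sub_rate or ins_rate or del_rate or max_softclip):
        raise SimError("error injection supports DNA datasets only")
    if not (sub_rate or ins_rate or del_rate or max_softclip):
        return dataset
    rng = np.random.default_rng(seed)
    stride = dataset.params.stride
    trim = dataset.params.trim_samples
    new_reads = []
    for sr in dataset.reads:
        old = sr.sig2read
        old_slots = [op.length // stride for op in old.ops]
        # units: one per basecalled read base, in sequencing order
        # each unit: (base, slots, kind) where kind M (ref base) or I (hallucinated)
        units: list[tuple[str, int, str]] = []
        pending_slots = 0  # strides of bases deleted before any kept base
        for b, s in zip(sr.record.sequence, old_slots):
            if rng.random() < del_rate:
                # missed base: its strides merge into the previous kept base
                for j in range(len(units) - 1, -1, -1):
                    if units[j][2] in "MI":
                        units[j] = (units[j][0], units[j][1] + s, units[j][2])
                        break
                else:
                    pending_slots += s
                units.append(("", 0, "D"))
                continue
            if rng.random() < sub_rate:
                b = BASES[(_BASE_VAL[b] + int(rng.integers(1, 4))) % 4]
            units.append((b, s + pending_slots, "M"))
            pending_slots = 0
            if s >= 2 and rng.random() < ins_rate:
                take = int(rng.integers(1, s))
                prev = units[-1]
                units[-1] = (prev[0], prev[1] - take, "M")
                units.append((BASES[int(rng.integers(0, 4))], take, "I"))
        if not any(u[2] in "MI" for u in units):
            raise SimError(f"read {sr.record.read_id}: error injection removed "
                           "every base (empty read)")

        read_bases = [u for u in units if u[2] in "MI"]
        read_seq = "".join(u[0] for u in read_bases)
        slots = np.array([u[1] for u in read_bases], dtype=np.int64)
        if (slots < 1).any():
            raise SimError("internal: zero-stride base after error injection")

        # CIGAR in read (sequencing) orientation
        cig_units = [u[2] for u in units]
        c1 = int(rng.integers(0, max_softclip + 1)) if max_softclip else 0
        c2 = int(rng.integers(0, max_softclip + 1)) if max_softclip else 0
        if c1 + c2 >= len(read_seq):
            c1 = c2 = 0
        cig_units, lead_ref_skip, tail_ref_skip = _apply_clips(cig_units, c1, c2)
        if sr.record.strand == "-":
            cig_aln = cig_units[::-1]
            ref_start = sr.record.ref_start + tail_ref_skip
        else:
            cig_aln = cig_units
            ref_start = sr.record.ref_start + lead_ref_skip
        cigar = _merge_cigar(cig_aln)

        moves = np.zeros(int(slots.sum()), dtype=np.int8)
        moves[np.concatenate([[0], np.cumsum(slots)[:-1]])] = 1
        mt = MoveTable(stride=stride, moves=moves, trim_samples=trim)

        dwells = slots * stride
        sig_start = trim
        sig_end = trim + int(dwells.sum())
        match_ops = tuple(SsOp(OpKind.MATCH, int(d)) for d in dwells)
        sig2read = SsAlignment(old.read_id, match_ops, sig_start, sig_end,
                               0, len(read_seq), "read",
                               sr.record.strand, "forward")
        sig2ref = _project_truth(sig2read, cig_units, dwells, ref_start,
                                 sr.record.strand, dataset.ref_name)

        rec = copy.deepcopy(sr.record)
        rec.sequence = read_seq
        rec.cigar = cigar
        rec.ref_start = ref_start
        rec.set_tag("mv", mt.to_tag(), "B")
        new_reads.append(SimRead(rec, sr.signal, mt, sig2read, sig2ref,
                                 sr.is_modified))
    return SimulatedDataset(dataset.reference, dataset.ref_name, dataset.model,
                            new_reads, dataset.params)


def _apply_clips(cig_units: list[str], c1: int, c2: int
                 ) -> tuple[list[str], int, int]:
    """Convert the first c1 / last c2 query bases to S; return the new unit
    list plus ref bases skipped at each end (from clipped M and dropped D)."""
    units = list(cig_units)

    def clip_front(units: list[str], count: int) -> tuple[list[str], int]:
        out, skipped, clipped = [], 0, 0
        idx = 0
        while idx < len(units) and clipped < count:
            u = units[idx]
            if u == "M":
                out.append("S")
                skipped += 1
                clipped += 1
            elif u == "I":
                out.append("S")
                clipped += 1
            else:  # D adjacent to a clip is dropped
                skipped += 1
            idx += 1
        # drop any D immediately after the clipped prefix
        while idx < len(units) and units[idx] == "D":
            skipped += 1
            idx += 1
        return out + units[idx:], skipped

    units, lead = clip_front(units, c1)
    units, tail = clip_front(units[::-1], c2)
    return units[::-1], lead, tail


def _merge_cigar(units: Sequence[str]) -> str:
    out = []
    for u in units:
        if out and out[-1][1] == u:
            out[-1][0] += 1
        else:
            out.append([1, u])
    return "".join(f"{n}{u}" for n, u in out)


def _project_truth(sig2read: SsAlignment, cig_units_read_order: list[str],
                   dwells: np.ndarray, ref_start: int, strand: str,
                   ref_name: str) -> SsAlignment:
    """Independent construction of the expected signal-to-reference truth by a
    straight unit walk (deliberately not sharing code with realign)."""
    ops: list[SsOp] = []
    q = 0  # read base index in sequencing order
    clipped_head = clipped_tail = 0
    seen_anchor = False
    for u in cig_units_read_order:
        if u == "M":
            ops.append(SsOp(OpKind.MATCH, int(dwells[q])))
            q += 1
            seen_anchor = True
        elif u == "I":
            if ops and ops[-1].kind is OpKind.SIG_INS:
                ops[-1] = SsOp(OpKind.SIG_INS, ops[-1].length + int(dwells[q]))
            else:
                ops.append(SsOp(OpKind.SIG_INS, int(dwells[q])))
            q += 1
        elif u == "D":
            if ops and ops[-1].kind is OpKind.BASE_DEL:
                ops[-1] = SsOp(OpKind.BASE_DEL, ops[-1].length + 1)
            else:
                ops.append(SsOp(OpKind.BASE_DEL, 1))
        else:  # S
            if seen_anchor:
                clipped_tail += int(dwells[q])
            else:
                clipped_head += int(dwells[q])
            q += 1
    sig_start = sig2read.sig_start + clipped_head
    sig_end = sig2read.sig_end - clipped_tail
    n_ref = sum(1 if op.kind is OpKind.MATCH else op.length
                for op in ops if op.kind is not OpKind.SIG_INS)
    return SsAlignment(sig2read.read_id, tuple(ops), sig_start, sig_end,
                       ref_start, ref_start + n_ref, "reference", strand,
                       "forward", ref_name=ref_name)
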