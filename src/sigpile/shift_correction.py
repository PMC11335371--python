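"""K-mer-to-base shift correction.

Signal aligners anchor current events to k-mers, not to single bases: the
event recorded at sequence position *j* reflects the k bases occupying the
pore, conventionally labelled by the k-mer starting at *j*.  Within that
k-mer one position — the most significant base (MSB) — dominates the current
level, so there is a systematic lag ``m < k`` between a base and the event
that best represents it.  The lag is protocol-specific (flow cell, basecaller
model, aligner) and must be measured per dataset.

Two estimators live here:

* :func:`msb_position` finds the MSB of a pore model alone: for each k-mer
  position, partition all model mean levels by the base at that position and
  score the partition by eta-squared (between-group variance over total
  variance).  A score of 1 means the level is a pure function of that
  position's base.
* :func:`calculate_offset` measures the shift empirically from aligned data:
  for each candidate shift ``s`` in ``[0, k)`` it re-pairs every event with
  the base ``s`` positions downstream (in molecule orientation) and scores
  how well the per-event mean currents separate by base identity.  The true
  lag maximizes the separation, because only then is each event grouped by
  the base that actually dominates it.

:func:`apply_shift` performs the re-pairing on one alignment: the op
previously paired with base *i* pairs with base *i + shift* (reference
coordinates; mirrored for − strand reads, whose k-mers run the other way
along the reference).  The trailing ``shift`` ops lose their base and are
dropped, and the leading ``shift`` bases become unpaired and are trimmed from
the sequence span.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .formats_io import PoreModel, RawSignal
from .realign import ensure_oriented, is_oriented, orient_for_reference
from .ss_codec import OpKind, SsAlignment, SsOp, sample_slices

COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


class ShiftError(ValueError):
    pass


@dataclass
class OffsetReport:
    """Result of dataset-wide offset calibration."""

    candidate_shifts: list[int]
    separation_scores: list[float]
    chosen_shift: int
    protocol_label: str = ""
    low_confidence: bool = False
    n_ops: int = 0
    details: dict | None = field(default=None, repr=False)

    def to_json(self) -> str:
        return json.dumps({
            "candidate_shifts": self.candidate_shifts,
            "separation_scores": [round(float(s), 6) for s in self.separation_scores],
            "chosen_shift": self.chosen_shift,
            "protocol_label": self.protocol_label,
            "low_confidence": self.low_confidence,
            "n_ops": self.n_ops,
        }, indent=2, sort_keys=True)


def _eta_squared(values: np.ndarray, labels: np.ndarray) -> float:
    """Between-group variance of group means over total variance (one-way eta²)."""
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    if ss_total == 0.0:
        return 0.0
    ss_between = 0.0
    for lab in np.unique(labels):
        grp = values[labels == lab]
        ss_between += len(grp) * (grp.mean() - grand) ** 2
    return float(ss_between / ss_total)


def msb_position(model: PoreModel) -> tuple[int, np.ndarray]:
    """Most significant base of a pore model, with the per-position score vector.

    Requires a complete (4**k entry) model; a model whose levels carry no
    variance at all is rejected as degenerate.  Ties break to the smallest
    position.
    """
    if not model.complete or len(model.levels) != 4 ** model.k:
        raise ShiftError(f"msb_position needs a complete model "
                         f"({len(model.levels)}/{4 ** model.k} k-mers present)")
    kmers = sorted(model.levels)
    levels = np.array([model.levels[km][0] for km in kmers])
    if np.ptp(levels) == 0:
        raise ShiftError("degenerate model: identical level for all k-mers")
    scores = np.empty(model.k)
    for p in range(model.k):
        labels = np.frombuffer("".join(km[p] for km in kmers).encode(), dtype="S1")
        scores[p] = _eta_squared(levels, labels)
    return int(np.argmax(scores)), scores


def apply_shift(alignment: SsAlignment, shift: int) -> SsAlignment:
    """Advance the base↔op pairing of one signal-to-reference alignment.

    Returns a new alignment in the same op-order convention as the input.
    ``shift`` must be smaller than the number of MATCH ops.
    """
    if alignment.seq_kind != "reference":
        raise ShiftError("apply_shift needs a signal-to-reference alignment")
    if shift < 0:
        raise ShiftError(f"shift must be >= 0, got {shift}")
    if shift == 0:
        return alignment
    if shift >= alignment.n_match:
        raise ShiftError(f"shift {shift} >= {alignment.n_match} MATCH ops")

    already_oriented = is_oriented(alignment)
    oriented = ensure_oriented(alignment)
    # + strand: events lag downstream -> coverage moves up; clip the tail.
    # - strand: molecule runs the other way -> coverage moves down; clip the head.
    if alignment.strand == "+":
        ops, _ = _clip_seq_units(list(oriented.ops), shift, from_tail=True)
        seq_start, seq_end = oriented.seq_start + shift, oriented.seq_end
        kept_slices = sample_slices(oriented)[:len(ops)]
    else:
        ops, _ = _clip_seq_units(list(oriented.ops), shift, from_tail=False)
        seq_start, seq_end = oriented.seq_start, oriented.seq_end - shift
        all_slices = sample_slices(oriented)
        kept_slices = all_slices[len(all_slices) - len(ops):]
    if not any(op.kind is OpKind.MATCH for op in ops):
        raise ShiftError("shift leaves no MATCH ops")

    # Recompute the signal span from the surviving ops' sample slices.
    sampled = [s for s in kept_slices if s is not None]
    sig_start = min(s for s, _ in sampled)
    sig_end = max(e for _, e in sampled)

    out = oriented.replaced(ops=tuple(ops), seq_start=seq_start, seq_end=seq_end,
                            sig_start=sig_start, sig_end=sig_end)
    if not already_oriented:
        out = orient_for_reference(out)  # restore the caller's op-order convention
    return out


def _clip_seq_units(ops: list[SsOp], units: int, from_tail: bool) -> tuple[list[SsOp], int]:
    """Drop ops from one end until ``units`` sequence bases are removed.

    SIG_INS ops encountered on the way are dropped with them; a BASE_DEL may
    be split.  Returns the surviving ops and the number of units removed.
    """
    if not from_tail:
        clipped, n = _clip_seq_units(ops[::-1], units, from_tail=True)
        return clipped[::-1], n
    removed = 0
    out = list(ops)
    while out and removed < units:
        op = out[-1]
        if op.kind is OpKind.SIG_INS:
            out.pop()
        elif op.kind is OpKind.MATCH:
            out.pop()
            removed += 1
        else:  # BASE_DEL
            take = min(op.length, units - removed)
            removed += take
            if take == op.length:
                out.pop()
            else:
                out[-1] = SsOp(OpKind.BASE_DEL, op.length - take)
    return out, removed


def calculate_offset(alignments: list[SsAlignment],
                     signals: dict[str, RawSignal],
                     reference: str,
                     model: PoreModel,
                     protocol_label: str = "",
                     max_ops: int = 50_000,
                     seed: int = 0,
                     collect_details: bool = False) -> OffsetReport:
    """Measure the dataset-wide k-mer-to-base shift.

    For every candidate shift ``s`` in ``[0, k)``: apply :func:`apply_shift`
    to each alignment, take the mean pico-amp current of every MATCH op, and
    group those means by the base as read by the pore (the reference base for
    + strand ops, its complement for − strand ops — pooling by raw reference
    base would mix the two strands' level distributions and mask the
    separation).  The separation score is the same eta-squared statistic as
    :func:`msb_position`; the chosen shift maximizes it, ties breaking low.

    When more than ``max_ops`` MATCH ops are available a seeded subsample of
    that size is scored instead.
    """
    if not alignments:
        raise ShiftError("calculate_offset needs at least one alignment")
    k = model.k
    pA_cache: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    scores: list[float] = []
    details: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    observed_bases: set[str] = set()
    n_ops_used = 0
    for s in range(k):
        means: list[float] = []
        bases: list[str] = []
        for aln in alignments:
            try:
                shifted = apply_shift(aln, s)
            except ShiftError:
                continue
            sig = signals[aln.read_id]
            if aln.read_id not in pA_cache:
                pA_cache[aln.read_id] = sig.to_pA().astype(np.float64)
            pA = pA_cache[aln.read_id]
            oriented = ensure_oriented(shifted)
            slices = sample_slices(oriented)
            x = oriented.seq_start
            for op, sl in zip(oriented.ops, slices):
                if op.kind is OpKind.MATCH:
                    if 0 <= x < len(reference):
                        base = reference[x]
                        if aln.strand == "-":
                            base = base.translate(COMPLEMENT)
                        means.append(float(pA[sl[0]:sl[1]].mean()))
                        bases.append(base)
                    x += 1
                elif op.kind is OpKind.BASE_DEL:
                    x += op.length
        if not means:
            scores.append(0.0)
            continue
        values = np.asarray(means)
        labels = np.asarray(bases)
        if len(values) > max_ops:
            idx = rng.choice(len(values), size=max_ops, replace=False)
            values, labels = values[idx], labels[idx]
        observed_bases.update(np.unique(labels).tolist())
        n_ops_used = max(n_ops_used, len(values))
        scores.append(_eta_squared(values, labels))
        if collect_details:
            details[s] = (values, labels)

    if not any(scores):
        raise ShiftError("no usable MATCH ops in any alignment")
    low_conf = len(observed_bases) < 4
    if low_conf:
        warnings.warn(f"only {len(observed_bases)} distinct bases observed; "
                      "offset estimate is low-confidence")
    chosen = int(np.argmax(scores))
    return OffsetReport(
        candidate_shifts=list(range(k)),
        separation_scores=[float(s) for s in scores],
        chosen_shift=chosen,
        protocol_label=protocol_label or model.name,
        low_confidence=low_conf,
        n_ops=n_ops_used,
        details=details if collect_details else None,
    )


def plot_offset_densities(report: OffsetReport, out_path: str) -> None:
    """Per-shift, per-base density plot of event mean currents (PDF/PNG).

    Requires a report built with ``collect_details=True``.
    """
    if not report.details:
        raise ShiftError("report carries no per-shift details; "
                         "rerun calculate_offset(collect_details=True)")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shifts = sorted(report.details)
    fig, axes = plt.subplots(len(shifts), 1, figsize=(6, 2.2 * len(shifts)),
                             sharex=True, squeeze=False)
    for ax, s in zip(axes[:, 0], shifts):
        values, labels = report.details[s]
        for base in sorted(set(labels.tolist())):
            ax.hist(values[labels == base], bins=40, density=True,
                    histtype="step", label=base)
        ax.set_ylabel(f"shift {s}\nscore {report.separation_scores[s]:.3f}")
        if s == shifts[0]:
            ax.legend(fontsize=7, ncol=4)
    axes[-1, 0].set_xlabel("event mean current (pA)")
    fig.suptitle(f"offset calibration: chosen shift {report.chosen_shift} "
                 f"({report.protocol_label})")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
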