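# Methods

## Signal model and coordinate conventions

All coordinates are 0-based half-open internally; SAM's 1-based POS and the
CLI's `name:start-end` region syntax (1-based inclusive) are converted at the
boundary. Raw samples are DAC units with per-read calibration
`pA = (raw + offset_pA) * range_pA / digitisation`. The container accepts
float samples; the simulator writes floats under an identity calibration
(digitisation = range, offset 0) so noise-free fixtures reproduce model means
exactly, while real integer DAC data round-trips unchanged.

An ss alignment is an op list (MATCH of n samples on one base, SIG_INS of n
samples on no base, BASE_DEL of m bases with no samples) plus signal and
sequence spans. Canonical form forbids adjacent SIG_INS or adjacent BASE_DEL
ops; adjacent MATCH ops are the normal encoding since each binds exactly one
base. Two conservation laws (samples vs signal span, bases vs sequence span)
are enforced by `validate` and hold for every producer in the package.

`signal_direction` records whether op order runs with (`forward`) or against
(`reverse`) raw acquisition order. DNA − strand alignments come out of
`realign` in read sequencing order (`forward`, decreasing reference
coordinate); `orient_for_reference` flips them for layout. Direct RNA is
basecalled 5'→3' while acquired 3'→5', so `reform --rna` emits
`reverse` directly.

## reform

Base *i* of the basecalled read owns samples
`[trim + stride*slot_i, trim + stride*slot_{i+1})` where `slot_i` is the
position of the i-th move flag. Samples beyond the last stride slot are
unmodeled by the basecaller and are excluded rather than appended to the
last base: attributing unmodeled signal to a base would bias its dwell and
mean level. Move tables are surjective onto bases, so reform never emits
SIG_INS or BASE_DEL.

## realign

The signal-to-read alignment is composed with the read-to-reference CIGAR by
a single walk in alignment orientation. Reference bases consumed by `M/=/X`
keep their read base's samples; `I` bases contribute SIG_INS ops between the
flanking MATCH ops (so the renderer can stack them at the border of the
preceding reference base, rather than silently inflating a neighbour's
dwell); `D/N` become BASE_DEL, with `N` spans recorded separately so a
renderer can draw intron skips differently; `S` samples are trimmed from the
signal span (clipped signal is not reference-anchored). A read base with
zero dwell maps to a 1-base BASE_DEL. Hard clips with full-read signal are a
hard error — the composition would be ill-defined.

Equivalence with an independent per-sample projection (each sample mapped
through read base → CIGAR unit → reference position or gap, with no shared
code) is checked on 500 fuzzed (dwell, CIGAR) pairs including I/D/S/N and
both strands, in the test suite and in `scripts/acceptance.py`.

## K-mer-to-base shift correction

Event-based aligners anchor the event at sequence position *j* to the k-mer
starting at *j* (the move-table/eventalign convention, which the simulator
reproduces). The current level of that event is dominated by one k-mer
position — the most significant base (MSB). Consequently the event that best
represents base *b* sits at position *b − m* for MSB position *m*, and the
whole dataset should be re-paired by *m*.

Both estimators use one-way eta-squared (between-group variance of group
means, weighted by group size, over total variance) as the separation
statistic: it is bounded in [0, 1], equals 1 iff the level is a pure function
of the grouping base, and is trivially brute-force checkable.

* `msb_position` groups the 4^k model means by the base at each position;
  the MSB is the argmax (ties to the smallest position). A model with zero
  level variance is rejected as degenerate.
* `calculate_offset` tries every shift s in [0, k): it applies `apply_shift`
  to each alignment, computes each MATCH op's mean pA, and groups the means
  by the base *as read by the pore* — the reference base for + ops, its
  complement for − ops. Pooling both strands by raw reference base would mix
  the level distributions of complementary bases and mask the separation.
  Because the grouping base at shift s is exactly k-mer position s of the
  event's k-mer, the score vector over shifts mirrors the model's
  per-position variance shares, and the argmax recovers the MSB.
  More than 50,000 usable ops are subsampled (seeded) for speed; fewer than
  4 distinct observed bases flags the report low-confidence. The report
  carries a protocol label so stored offsets are never silently reused
  across chemistries.

`apply_shift` advances the pairing: the op paired with base *i* re-pairs with
base *i + s* (mirrored along the reference for − strand reads, whose k-mers
run the other way). The trailing s ops lose their base and are dropped, the
leading s bases are trimmed, and conservation is re-established by
recomputing the spans from the surviving ops' sample slices. The direction
follows from the k-mer-start anchoring above: the relevant event for a base
lies downstream of it, so correction moves ops toward lower coordinates.
The viewer pipeline applies the calibrated shift automatically when a pore
model is supplied (`--no-shift` or an explicit `--shift N` overrides).

## Pileup layout and rendering

Time-scale places the i-th plotted sample at `i * unit`; molecule-scale
gives every base an equal-width column and packs a base's n samples at
`left + width * (j + ½)/n`, which is what lets reads with different
translocation speeds overlay. Region clipping keeps whole base columns;
SIG_INS at a kept boundary rides along, deleted bases leave labelled gaps.
Stacked tracks use first-fit interval packing so rows never overlap; track
order is annotation, simulated, + overlay, + stack, − overlay, − stack.

The HTML view is a single self-contained file: one JSON payload (sorted
keys, full float precision — the renderer never rounds or rescales pA
values) plus ~150 lines of vanilla JS for pan/zoom, read select/deselect
driving overlay membership, and a "show signal points" toggle revealing
stacked insertion samples. With a fixed build stamp, re-rendering the same
layout is byte-identical, which makes the full pipeline's output diffable.
The A/C/G/T(U) palette is fixed and documented in `render.BASE_COLORS`, with
a colour-blind-safe alternative behind `palette="colorblind"`. A static SVG
export provides figure output.

## Simulator

The simulator exists so that every component can be tested against known
truth without instrument data. Per read: a uniform sub-span of the reference
and a strand (default half +); per base, dwell = stride × (1 + NB(mean
(dwell_mean/stride) − 1, dispersion)) — a truncated negative binomial with
minimum one stride, reflecting that move tables quantize dwell to stride
multiples; per sample, current ~ Normal(k-mer model mean (+Δ at modified
positions on modified reads), model sd × noise multiplier). Defaults: 9
samples/base mean dwell, dispersion 3, stride 5, noise multiplier 1, 20
adapter samples trimmed, a few trailing unmodeled samples, 4 kHz sampling.
K-mers are anchored at their first base in read orientation; read ends are
padded with `A` so terminal bases still have a k-mer (an edge effect spanning
k−1 bases per read end).

Synthetic pore models place a designated MSB: level = 85 + 12·v(base at MSB)
+ 0.8·v(other bases) + N(0, 0.3) pA with v(A..T) = 0..3 and sd 1.5 pA —
roughly the level spread and within-event noise scale of real pore models,
with ~97% of level variance attributable to the MSB so that calibration is
identifiable at desk-scale depth. Setting the minor weight and level noise
to zero gives a pure-position model with an exact closed-form score of 1.

`inject_errors` mutates basecalls while keeping the bundle self-consistent:
a missed (deleted) base's strides merge into the previous kept base, a
hallucinated (inserted) base splits strides off a donor base, substitutions
change sequence only, and terminal soft clips keep their signal. Move
tables, CIGARs and ground-truth ss alignments are re-derived by an
independent unit walk (deliberately not sharing code with `realign`, so the
two can be compared in tests).

What the simulator does *not* model: amplitude drift, pore stalls and
blockages, real adapter waveforms, homopolymer-specific dwell behaviour,
context-dependent basecall error profiles, or the exact level statistics of
any real chemistry. Passing tests therefore demonstrate the correctness of
the alignment algebra, the identifiability of the shift under the stated
generative model, and the fidelity of the rendering pipeline — not
performance on real flow-cell data.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen to
make every property sharply decidable: ≥1000 fuzzed codec round trips, ≥500
fuzzed move tables and (dwell, CIGAR) projection cases, and 100 seeded
simulation replicates at 500 reference bases × 20× depth for shift recovery
(each replicate ~10 k events, far above what the η² contrast needs). All
randomness flows from explicit seeds; the full pipeline is byte-reproducible,
which the suite verifies by diffing complete output files.

## Known limitations

* PAF records carry no per-base sequence, so PAF round trips preserve
  coordinates, CIGAR (via `cg:Z`) and tags but not the query sequence.
* `calculate_offset` assumes signal-to-reference input; signal-to-read
  alignments must be realigned first.
* Region queries are linear scans — exact and fast at desk scale, not
  indexed for whole-genome BAMs.
* The RNA path (reverse acquisition order) is simulated and tested for the
  reform/layout algebra, but error injection supports DNA only.
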