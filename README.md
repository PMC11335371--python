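# sigpile

**Sequence-anchored visualization of nanopore raw signal data.**

Nanopore instruments record a time series of ionic current (a "squiggle") as
each DNA or RNA molecule translocates a pore. The squiggle carries more
information than the basecalled sequence — base modifications such as 5mC or
pseudouridine, secondary structure, damage — but it is large, noisy, and hard
to read without anchoring every raw sample to the base it measured. sigpile
is a toolkit for exactly that anchoring, and for browsing the result: it
aligns raw samples to basecalled reads or a reference, encodes the alignment
compactly on standard SAM/PAF records, corrects the systematic k-mer-to-base
lag of event-based aligners, and renders multi-read **signal pileups** as a
self-contained interactive HTML view. It is aimed at people developing or
debugging signal-level methods (modification callers, basecallers, signal
simulators) and at anyone who wants to look at the evidence under a candidate
variant or modified site.

## The ss encoding

A signal-to-sequence alignment is an ordered op list carried in an `ss:Z:`
auxiliary tag, one glyph per op, inspired by the CIGAR string:

| glyph | op       | meaning                                    |
|-------|----------|--------------------------------------------|
| `n,`  | MATCH    | *n* consecutive samples on exactly one base |
| `nI`  | SIG_INS  | *n* samples aligned to no base             |
| `mD`  | BASE_DEL | *m* bases with no signal                   |

`"8,5I4,2D6,"` reads: 8 samples on a base, 5 inserted samples, 4 samples on
the next base, 2 bases without signal, 6 samples on the following base.
A companion `si:Z:sig_start,sig_end,seq_start,seq_end` tag pins the aligned
spans (0-based, half-open). Two conservation laws make the encoding checkable:
MATCH+SIG_INS samples must equal the signal span, and MATCH count plus
BASE_DEL bases must equal the sequence span. This grammar is normative for
sigpile; any aligner whose output is expressed in it can feed the viewer.

## Components

- **reform** — converts a basecaller move table (`mv:B:c` stride-prefixed
  flags, `ts:i` trim) into a signal-to-read ss alignment: base *i* owns the
  samples between its move flag and the next.
- **realign** — composes that with the read's CIGAR to get signal-to-reference
  coordinates: CIGAR `I`/`S` read bases become SIG_INS / trimmed samples,
  `D`/`N` become BASE_DEL gaps; − strand alignments are re-oriented so columns
  line up across strands.
- **calculate-offsets** — k-mer-to-base shift correction. Event aligners
  anchor events to k-mers, so each base lags its most relevant event by the
  position of the k-mer's *most significant base* (MSB) — the base that
  dominates the current level. For each candidate shift s < k the tool
  re-pairs events with the base s positions downstream and scores how well
  per-event mean currents separate by base identity (one-way
  η² = between-group / total variance); the true lag maximizes the score.
  The lag is protocol-specific and the report is labelled accordingly.
- **pileup + render** — molecule-scale layout (every base column equal width)
  so independent reads overlay despite variable dwell; per-strand stacked
  tracks, a shared overlay, BED annotation and simulated-data tracks; output
  is one self-contained interactive HTML file (pan/zoom, read
  select/deselect, "show signal points" for stacked insertions) or static SVG.
- **simulator** — a fully seeded pore-model signal simulator (Gaussian k-mer
  levels, truncated-negative-binomial dwells, adapter trim, both strands,
  variants, modification level offsets, basecall-error injection) that emits
  every input format plus ground-truth ss alignments, so the whole toolkit is
  testable without instrument data.

## Worked example

```sh
sigpile simulate --ref-len 200 --depth 4 --kmer 4 --msb 2 --seed 7 --outdir fix/
sigpile reform   --bam fix/reads.sam --signal fix/signals.tsv -o s2read.sam
sigpile realign  --sig2read s2read.sam -o s2ref.sam
sigpile calculate-offsets --sam s2ref.sam --signal fix/signals.tsv \
        --ref fix/ref.fa --model fix/model.tsv -o report.json
sigpile plot --region ref1:41-160 --sam s2ref.sam --signal fix/signals.tsv \
        --ref fix/ref.fa --model fix/model.tsv -o view.html
```

or from Python (`examples/02_shift_correction.py`):

```
protocol-msb1: model MSB at position 1 (scores [0.004, 0.982, 0.004, 0.004, 0.004])
  calibrated shift: 1 (separation scores [0.001, 0.98, 0.003, 0.008, 0.025])

protocol-msb3: model MSB at position 3 (scores [0.004, 0.004, 0.004, 0.982, 0.004])
  calibrated shift: 3 (separation scores [0.01, 0.001, 0.003, 0.982, 0.002])
```

The model MSB score says how much of the level table's variance the base at
each k-mer position explains; the calibrated shift recovers that position
from raw aligned data alone, and differs between the two emulated protocols —
which is why sigpile recalibrates per dataset instead of reusing offsets.
`examples/01_signal_to_reference.py` walks the reform→realign path and prints
the ss/si tags; `examples/03_pileup_view.py` renders a case-vs-control pileup
around a +8 pA modified site.

## File formats

FASTA (pyfaidx-indexed), plain-text SAM and PAF with `ss`/`si`/`mv`/`ts`
tags, BED3+, pore-model TSV (`kmer  level_mean  level_stdv`), and a
documented plain-text signal container: two header lines, then one TSV line
per read — `read_id  digitisation  offset_pA  range_pA  sampling_rate
samples` with comma-separated samples, converted to pico-amps as
`pA = (raw + offset_pA) * range_pA / digitisation`. The container stands in
for binary squiggle archives; any reader producing the same
`{read_id: RawSignal}` mapping can be swapped in.

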