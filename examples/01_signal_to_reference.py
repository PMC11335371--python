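"""From move table to reference-anchored signal: simulate -> reform -> realign.

Simulates a tiny seeded dataset, converts one read's basecaller move table
into a signal-to-read alignment, projects it onto the reference through the
read's CIGAR, and prints the resulting ss/si tags.
"""

import sigpile as sp
from sigpile.realign import realign
from sigpile.reform import reform

model = sp.make_synthetic_model(k=4, msb=2, seed=0)
ds = sp.simulate_dataset(200, model, sp.SimParams(depth=3, seed=42))

read = ds.reads[0]
print(f"read {read.record.read_id}: {len(read.record.sequence)} bases, "
      f"{len(read.signal)} raw samples, strand {read.record.strand}")

sig2read = reform(read.move_table, read.record, read.signal)
print("signal-to-read  ss:", sp.emit_ss(sig2read)[:60], "...")
print("signal-to-read  si:", sp.emit_si(sig2read),
      "   (sig_start,sig_end,seq_start,seq_end)")
# each "n," glyph is one base dwelling for n raw samples; the leading samples
# before sig_start are the trimmed adapter

sig2ref = realign(sig2read, read.record)
print("signal-to-ref   si:", sp.emit_si(sig2ref),
      f"  (reference {sig2ref.ref_name}:{sig2ref.seq_start}-{sig2ref.seq_end})")
violations = sp.validate(sig2ref, len(read.signal), len(ds.reference))
print("conservation violations:", violations or "none")
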