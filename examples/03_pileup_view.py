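"""A case-vs-control signal pileup with an annotated modified site.

Simulates 30x coverage with a +8 pA level distortion at one reference
position on half the reads (the shape of a partially methylated CpG),
annotates the site with a BED interval, and renders the interactive HTML
browser view plus a static SVG.
"""

from pathlib import Path

import sigpile as sp
from sigpile.pileup import PileupOptions, build_pileup
from sigpile.render import export_svg, render_html
from sigpile.simulator import Modification

site = 120
model = sp.make_synthetic_model(k=4, msb=2, seed=0)
ds = sp.simulate_dataset(
    250, model,
    sp.SimParams(depth=30, seed=7, modifications=[Modification(site, 8.0, 0.5)]))

bed = Path("scratch_example.bed")
bed.write_text(f"ref1\t{site}\t{site + 1}\tmodified-site\n")

region = sp.Region("ref1", site - 25, site + 25)
options = PileupOptions(
    annotations=sp.read_bed(bed),
    # unmodified reads double as an "expected" track next to the pileup
    simulated=[(r.sig2ref, r.signal) for r in ds.reads if not r.is_modified][:3],
)
layout = build_pileup(region, [r.sig2ref for r in ds.reads if r.is_modified],
                      ds.signals, ds.reference, options)

html = render_html(layout, "pileup_view.html")
svg = export_svg(layout, "pileup_view.svg")
bed.unlink()
print(f"region ref1:{region.start + 1}-{region.end}  "
      f"({len(layout.glyphs)} modified reads in pileup, "
      f"{len(layout.sim_glyphs)} control reads as a parallel track)")
print("tracks:", [(t.kind, t.strand, len(t.members)) for t in layout.tracks])
print("wrote", html, "and", svg, "- open the HTML in a browser to pan/zoom,")
print("toggle reads, and reveal stacked insertion points")
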