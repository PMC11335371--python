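"""Render a :class:`~sigpile.pileup.PileupLayout` to a self-contained
interactive HTML file, or to a static SVG for figures.

The HTML file embeds one JSON payload per track plus a small vanilla-JS
viewer: pan (drag) and zoom (wheel) along the reference axis, per-read
select/deselect checkboxes driving overlay membership, a "show signal
points" toggle revealing insertion markers, and base-coloured column
backgrounds.  No server and no external assets, so the file can be shared
and archived; given a fixed ``build_stamp`` re-rendering the same layout is
byte-identical.

The renderer never alters numbers: pico-amp values are embedded at full
Python float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .pileup import PileupLayout, ReadGlyph

#: A/C/G/T(U) palette; ``colorblind`` swaps in an Okabe-Ito-based set.
BASE_COLORS = {
    "default": {"A": "#3aa661", "C": "#4a7bd4", "G": "#d4a43a", "T": "#d4533a",
                "U": "#d4533a", "N": "#999999"},
    "colorblind": {"A": "#009E73", "C": "#0072B2", "G": "#E69F00", "T": "#D55E00",
                   "U": "#D55E00", "N": "#999999"},
}


def _glyph_payload(g: ReadGlyph) -> dict:
    return {
        "read_id": g.read_id,
        "strand": g.strand,
        "polyline": [[x, y] for x, y in g.polyline],
        "columns": [[x0, x1, b] for x0, x1, b in g.columns],
        "gaps": [[x0, x1, lab] for x0, x1, lab in g.gap_spans],
        "ins": [[x, list(vals)] for x, vals in g.insertion_markers],
    }


def layout_payload(layout: PileupLayout) -> dict:
    """The JSON-serializable data payload embedded in the HTML view."""
    return {
        "region": {"ref_name": layout.region.ref_name,
                   "start": layout.region.start, "end": layout.region.end},
        "base_width": layout.base_width,
        "width": layout.width,
        "columns": [[x0, x1, b] for x0, x1, b in layout.columns],
        "tracks": [{"kind": t.kind, "strand": t.strand, "members": t.members,
                    "rows": t.rows, "n_rows": t.n_rows} for t in layout.tracks],
        "glyphs": {rid: _glyph_payload(g) for rid, g in sorted(layout.glyphs.items())},
        "sim_glyphs": {rid: _glyph_payload(g)
                       for rid, g in sorted(layout.sim_glyphs.items())},
        "annotations": [[x0, x1, lab, col] for x0, x1, lab, col in layout.annotations],
    }


_JS = r"""
'use strict';
const SVGNS = 'http://www.w3.org/2000/svg';
let viewX = 0, viewScale = 1, showPoints = false;
const selected = new Set(Object.keys(DATA.glyphs));

function el(tag, attrs, parent) {
  const e = document.createElementNS(SVGNS, tag);
  for (const k in attrs) e.setAttribute(k, attrs[k]);
  if (parent) parent.appendChild(e);
  return e;
}

function pARange() {
  let lo = Infinity, hi = -Infinity;
  const scan = g => {
    for (const [, y] of g.polyline) { if (y < lo) lo = y; if (y > hi) hi = y; }
    for (const [, vals] of g.ins) for (const y of vals) {
      if (y < lo) lo = y; if (y > hi) hi = y;
    }
  };
  Object.values(DATA.glyphs).forEach(scan);
  Object.values(DATA.sim_glyphs).forEach(scan);
  if (lo === Infinity) { lo = 0; hi = 1; }
  return [lo - 2, hi + 2];
}

const TRACK_H = 120, ROW_H = 60, ANN_H = 24, PAD = 4;

function trackHeight(t) {
  if (t.kind === 'annotation') return ANN_H;
  if (t.kind === 'stacked_reads') return t.n_rows * ROW_H;
  return TRACK_H;
}

function yMap(yLo, yHi, h) {
  return pa => h - (pa - yLo) / (yHi - yLo) * h;
}

function drawGlyph(group, g, yfun, cls) {
  if (!g.polyline.length) return;
  const pts = g.polyline.map(([x, y]) => `${x},${yfun(y)}`).join(' ');
  el('polyline', {points: pts, class: 'sig ' + cls, fill: 'none'}, group);
  for (const [x0, x1, lab] of g.gaps) {
    el('rect', {x: x0, y: 0, width: Math.max(x1 - x0, 1), height: 8,
                class: 'gap'}, group);
    const t = el('text', {x: (x0 + x1) / 2, y: 16, class: 'gaplab'}, group);
    t.textContent = lab;
  }
  if (showPoints) {
    for (const [x, vals] of g.ins)
      for (const y of vals)
        el('circle', {cx: x, cy: yfun(y), r: 2, class: 'inspt'}, group);
  }
}

function drawColumns(group, cols, h) {
  for (const [x0, x1, base] of cols) {
    el('rect', {x: x0, y: 0, width: x1 - x0, height: h,
                fill: PALETTE[base] || PALETTE.N, 'fill-opacity': 0.18}, group);
  }
}

function render() {
  const svg = document.getElementById('view');
  svg.textContent = '';
  const [yLo, yHi] = pARange();
  let y = 0;
  const root = el('g', {transform:
    `translate(${-viewX * viewScale},0) scale(${viewScale},1)`}, svg);
  for (const t of DATA.tracks) {
    const h = trackHeight(t);
    const g = el('g', {transform: `translate(0,${y})`}, root);
    el('rect', {x: 0, y: 0, width: DATA.width, height: h, class: 'trackbg'}, g);
    if (t.kind === 'annotation') {
      for (const [x0, x1, lab, col] of DATA.annotations) {
        el('rect', {x: x0, y: 4, width: x1 - x0, height: h - 8,
                    fill: col || '#444'}, g);
        const tx = el('text', {x: x1 + 2, y: h - 8, class: 'annlab'}, g);
        tx.textContent = lab;
      }
    } else if (t.kind === 'simulated') {
      drawColumns(g, DATA.columns, h);
      const yfun = yMap(yLo, yHi, h);
      for (const rid of t.members) drawGlyph(g, DATA.sim_glyphs[rid], yfun, 'sim');
    } else if (t.kind === 'pileup_overlay') {
      drawColumns(g, DATA.columns, h);
      const yfun = yMap(yLo, yHi, h);
      for (const rid of t.members)
        if (selected.has(rid)) drawGlyph(g, DATA.glyphs[rid], yfun, 'ovl');
    } else {
      for (const rid of t.members) {
        if (!selected.has(rid)) continue;
        const row = t.rows[rid] || 0;
        const rg = el('g', {transform: `translate(0,${row * ROW_H})`}, g);
        drawColumns(rg, DATA.glyphs[rid].columns, ROW_H - PAD);
        drawGlyph(rg, DATA.glyphs[rid], yMap(yLo, yHi, ROW_H - PAD), 'stk');
      }
    }
    const lab = el('text', {x: 4, y: 12, class: 'tracklab'}, g);
    lab.textContent = t.kind + (t.strand !== 'both' ? ' (' + t.strand + ')' : '');
    y += h + PAD;
  }
  svg.setAttribute('height', Math.max(y, 40));
}

function buildControls() {
  const panel = document.getElementById('reads');
  for (const rid of Object.keys(DATA.glyphs).sort()) {
    const label = document.createElement('label');
    const cb = document.createElement('input');
    cb.type = 'checkbox'; cb.checked = true;
    cb.addEventListener('change', () => {
      cb.checked ? selected.add(rid) : selected.delete(rid);
      render();
    });
    label.appendChild(cb);
    label.appendChild(document.createTextNode(
      rid + ' (' + DATA.glyphs[rid].strand + ')'));
    panel.appendChild(label);
  }
  document.getElementById('showpoints').addEventListener('change', e => {
    showPoints = e.target.checked; render();
  });
}

function wirePanZoom() {
  const svg = document.getElementById('view');
  let dragging = false, lastX = 0;
  svg.addEventListener('wheel', e => {
    e.preventDefault();
    const f = e.deltaY < 0 ? 1.2 : 1 / 1.2;
    const mx = e.offsetX / viewScale + viewX;
    viewScale = Math.max(0.05, Math.min(50, viewScale * f));
    viewX = mx - e.offsetX / viewScale;
    render();
  });
  svg.addEventListener('mousedown', e => { dragging = true; lastX = e.clientX; });
  window.addEventListener('mouseup', () => { dragging = false; });
  window.addEventListener('mousemove', e => {
    if (!dragging) return;
    viewX -= (e.clientX - lastX) / viewScale;
    lastX = e.clientX;
    render();
  });
}

if (Object.keys(DATA.glyphs).length === 0 &&
    Object.keys(DATA.sim_glyphs).length === 0) {
  document.getElementById('empty').style.display = 'block';
} else {
  buildControls(); wirePanZoom(); render();
}
"""

_CSS = """
body { font-family: sans-serif; margin: 0; display: flex; }
#main { flex: 1 1 auto; overflow-x: auto; padding: 8px; }
#panel { flex: 0 0 220px; border-left: 1px solid #ccc; padding: 8px;
         font-size: 12px; max-height: 100vh; overflow-y: auto; }
#panel label { display: block; }
#empty { display: none; padding: 2em; color: #666; }
.trackbg { fill: #fafafa; stroke: #ddd; }
.sig { stroke-width: 1; }
.ovl { stroke: #3556a8; stroke-opacity: 0.45; }
.stk { stroke: #223; }
.sim { stroke: #7a3aa6; }
.gap { fill: #bbb; }
.gaplab, .annlab, .tracklab { font-size: 9px; fill: #555; }
.inspt { fill: #c02020; }
h1 { font-size: 14px; }
"""


def render_html(layout: PileupLayout, out_path: str | Path,
                build_stamp: str | None = None,
                palette: str = "default") -> Path:
    """Write the interactive browser view as one self-contained HTML file."""
    out_path = Path(out_path)
    stamp = build_stamp if build_stamp is not None else f"sigpile-{__version__}"
    payload = layout_payload(layout)
    data_js = json.dumps(payload, separators=(",", ":"), sort_keys=True)
    palette_js = json.dumps(BASE_COLORS[palette], sort_keys=True)
    region = layout.region
    title = f"{region.ref_name}:{region.start + 1}-{region.end}"
    html = f"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>signal pileup {title}</title>
<!-- generated by {stamp} -->
<style>{_CSS}</style>
</head>
<body>
<div id="main">
<h1>signal pileup &mdash; {title} <small>({stamp})</small></h1>
<div id="empty">No reads overlap this region.</div>
<svg id="view" width="{layout.width if layout.width > 0 else 400}"></svg>
</div>
<div id="panel">
<label><input type="checkbox" id="showpoints"> show signal points</label>
<hr>
<div id="reads"></div>
</div>
<script>
const DATA = {data_js};
const PALETTE = {palette_js};
{_JS}
</script>
</body>
</html>
"""
    try:
        out_path.write_text(html)
    except OSError as e:
        raise OSError(f"cannot write HTML view to {out_path}: {e}") from e
    return out_path


def export_svg(layout: PileupLayout, out_path: str | Path,
               palette: str = "default",
               track_height: float = 120.0, row_height: float = 60.0) -> Path:
    """Static SVG export of the same geometry (for figures)."""
    colors = BASE_COLORS[palette]
    lo, hi = _pa_range(layout)
    parts: list[str] = []
    y = 0.0
    for t in layout.tracks:
        h = (24.0 if t.kind == "annotation"
             else t.n_rows * row_height if t.kind == "stacked_reads"
             else track_height)
        parts.append(f'<g transform="translate(0,{y})">')
        parts.append(f'<rect x="0" y="0" width="{layout.width}" height="{h}" '
                     'fill="#fafafa" stroke="#ddd"/>')
        if t.kind == "annotation":
            for x0, x1, lab, col in layout.annotations:
                parts.append(f'<rect x="{x0}" y="4" width="{x1 - x0}" '
                             f'height="{h - 8}" fill="{col or "#444"}"/>')
        else:
            glyphs = layout.sim_glyphs if t.kind == "simulated" else layout.glyphs
            if t.kind == "stacked_reads":
                for rid in t.members:
                    row_y = t.rows.get(rid, 0) * row_height
                    parts.append(f'<g transform="translate(0,{row_y})">')
                    parts.append(_svg_glyph(glyphs[rid], lo, hi, row_height - 4,
                                            colors, "#223"))
                    parts.append("</g>")
            else:
                for x0, x1, base in layout.columns:
                    parts.append(f'<rect x="{x0}" y="0" width="{x1 - x0}" '
                                 f'height="{h}" fill="{colors.get(base, colors["N"])}" '
                                 'fill-opacity="0.18"/>')
                stroke = "#7a3aa6" if t.kind == "simulated" else "#3556a8"
                for rid in t.members:
                    parts.append(_svg_glyph(glyphs[rid], lo, hi, h, colors, stroke))
        parts.append("</g>")
        y += h + 4
    svg = (f'<svg xmlns="http://www.w3.org/2000/svg" width="{max(layout.width, 400)}" '
           f'height="{max(y, 40)}">' + "".join(parts) + "</svg>")
    out_path = Path(out_path)
    out_path.write_text(svg)
    return out_path


def _pa_range(layout: PileupLayout) -> tuple[float, float]:
    vals = [y for g in list(layout.glyphs.values()) + list(layout.sim_glyphs.values())
            for _, y in g.polyline]
    if not vals:
        return 0.0, 1.0
    return min(vals) - 2, max(vals) + 2


def _svg_glyph(glyph: ReadGlyph, lo: float, hi: float, h: float,
               colors: dict, stroke: str) -> str:
    def ymap(pa: float) -> float:
        return h - (pa - lo) / (hi - lo) * h

    parts = []
    for x0, x1, base in glyph.columns:
        parts.append(f'<rect x="{x0}" y="0" width="{x1 - x0}" height="{h}" '
                     f'fill="{colors.get(base, colors["N"])}" fill-opacity="0.12"/>')
    if glyph.polyline:
        pts = " ".join(f"{x},{ymap(v)}" for x, v in glyph.polyline)
        parts.append(f'<polyline points="{pts}" fill="none" stroke="{stroke}" '
                     'stroke-width="1"/>')
    for x0, x1, lab in glyph.gap_spans:
        parts.append(f'<rect x="{x0}" y="0" width="{max(x1 - x0, 1)}" height="8" '
                     f'fill="#bbb"/><text x="{(x0 + x1) / 2}" y="16" '
                     f'font-size="9" fill="#555">{lab}</text>')
    return "".join(parts)
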