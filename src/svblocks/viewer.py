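"""Self-contained HTML table browser over rendered event images.

The page is a single file that works from the local filesystem: a table with
one row per rendered genomic window (chromosome, start, end, region size,
variant IDs, number of variants, sample ID), click-to-display of the row's
image, click-to-filter on variant ID / variant count / sample ID, and a
filter window for region-size ranges and target chromosomes.  The filter
semantics are implemented once in :func:`filter_rows` and mirrored by the
generated JavaScript, so they are unit-testable without a browser.
"""

from __future__ import annotations

import html
import json
import logging
import os
from dataclasses import asdict, dataclass, field

from .model import contig_sort_key

log = logging.getLogger(__name__)


@dataclass
class ViewerIndexRow:
    chrom: str  # primary chromosome (first in contig order)
    start: int
    end: int
    region_size: int  # sum of window spans across chromosomes
    variant_ids: list = field(default_factory=list)
    n_variants: int = 0
    sample_id: str = ""
    image_path: str = ""
    chroms: list = field(default_factory=list)  # every chromosome touched


def build_index(json_docs, image_dir, image_ext: str = "svg",
                contig_order=None) -> list:
    """One row per rendered event across all documents, sorted by position.

    Events whose image is absent from ``image_dir`` (e.g. filtered at plot
    time) are skipped with a warning.
    """
    from .plotting import event_image_name

    rows = []
    for doc in json_docs:
        for net in doc.events:
            if not net.region:
                continue
            name = event_image_name(net, image_ext, contig_order)
            if not os.path.exists(os.path.join(str(image_dir), name)):
                log.warning("no image for event %s of %s; row skipped",
                            sorted(net.region), doc.sample_id)
                continue
            chroms = net.chroms(contig_order)
            primary = chroms[0]
            rows.append(ViewerIndexRow(
                chrom=primary,
                start=net.region[primary][0],
                end=net.region[primary][1],
                region_size=sum(e - s for s, e in net.region.values()),
                variant_ids=sorted(net.variant_ids),
                n_variants=len(net.variant_ids),
                sample_id=net.sample_id,
                image_path=name,
                chroms=chroms,
            ))
    rows.sort(key=lambda r: (contig_sort_key(r.chrom, contig_order), r.start,
                             r.sample_id))
    return rows


def filter_rows(rows, variant_id=None, sample_id=None, n_variants=None,
                size=None, chroms=None) -> list:
    """Apply the viewer's filters to an index.

    ``n_variants`` and ``size`` are inclusive (lo, hi) ranges (either bound
    may be None); ``chroms`` keeps rows touching *any* selected chromosome,
    so translocations stay visible under a single-chromosome filter.
    """
    out = []
    for row in rows:
        if variant_id is not None and variant_id not in row.variant_ids:
            continue
        if sample_id is not None and row.sample_id != sample_id:
            continue
        if n_variants is not None:
            lo, hi = n_variants
            if lo is not None and row.n_variants < lo:
                continue
            if hi is not None and row.n_variants > hi:
                continue
        if size is not None:
            lo, hi = size
            if lo is not None and row.region_size < lo:
                continue
            if hi is not None and row.region_size > hi:
                continue
        if chroms is not None and not set(row.chroms) & set(chroms):
            continue
        out.append(row)
    return out


def write_index_tsv(rows, path) -> None:
    header = ["chrom", "start", "end", "region_size", "variant_ids",
              "n_variants", "sample_id", "image_path", "chroms"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join([
                r.chrom, str(r.start), str(r.end), str(r.region_size),
                ",".join(r.variant_ids), str(r.n_variants), r.sample_id,
                r.image_path, ",".join(r.chroms),
            ]) + "\n")


_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>__TITLE__</title>
<style>
body { font-family: sans-serif; margin: 1em; color: #222; }
table { border-collapse: collapse; width: 100%; }
th, td { border: 1px solid #ccc; padding: 4px 8px; font-size: 13px; }
th { background: #2b3a67; color: white; cursor: pointer; }
tr:hover { background: #eef2ff; cursor: pointer; }
td.clickable { color: #2b3a67; text-decoration: underline; }
#filters { background: #f4f4f8; padding: 0.6em; margin-bottom: 1em;
           border: 1px solid #ccc; }
#filters label { margin-right: 1em; font-size: 13px; }
#filters input, #filters select { width: 7em; }
#image-panel img { max-width: 100%; border: 1px solid #ccc; margin-top: 1em; }
#count { font-size: 13px; color: #555; margin: 0.4em 0; }
</style>
</head>
<body>
<h2>__TITLE__</h2>
<div id="filters">
  <label>variant ID <input id="f-variant" type="text"></label>
  <label>sample ID <input id="f-sample" type="text"></label>
  <label>variants <input id="f-nvar-lo" type="number" placeholder="min">
         &ndash; <input id="f-nvar-hi" type="number" placeholder="max"></label>
  <label>region size (bp) <input id="f-size-lo" type="number" placeholder="min">
         &ndash; <input id="f-size-hi" type="number" placeholder="max"></label>
  <label>chromosomes <select id="f-chroms" multiple size="3"></select></label>
  <button onclick="clearFilters()">clear</button>
</div>
<div id="count"></div>
<table id="event-table">
<thead><tr><th>chrom</th><th>start</th><th>end</th><th>region size</th>
<th>variant IDs</th><th>n variants</th><th>sample</th></tr></thead>
<tbody></tbody>
</table>
<div id="image-panel"></div>
<script>
const ROWS = __ROWS__;
// Filter semantics mirror svblocks.viewer.filter_rows: inclusive ranges,
// chromosome filter keeps rows touching any selected contig.
function rowPasses(r, f) {
  if (f.variant !== null && !r.variant_ids.includes(f.variant)) return false;
  if (f.sample !== null && r.sample_id !== f.sample) return false;
  if (f.nvarLo !== null && r.n_variants < f.nvarLo) return false;
  if (f.nvarHi !== null && r.n_variants > f.nvarHi) return false;
  if (f.sizeLo !== null && r.region_size < f.sizeLo) return false;
  if (f.sizeHi !== null && r.region_size > f.sizeHi) return false;
  if (f.chroms !== null && f.chroms.length &&
      !r.chroms.some(c => f.chroms.includes(c))) return false;
  return true;
}
function currentFilters() {
  const num = id => {
    const v = document.getElementById(id).value;
    return v === "" ? null : Number(v);
  };
  const txt = id => {
    const v = document.getElementById(id).value.trim();
    return v === "" ? null : v;
  };
  const sel = Array.from(document.getElementById("f-chroms").selectedOptions)
                   .map(o => o.value);
  return {variant: txt("f-variant"), sample: txt("f-sample"),
          nvarLo: num("f-nvar-lo"), nvarHi: num("f-nvar-hi"),
          sizeLo: num("f-size-lo"), sizeHi: num("f-size-hi"),
          chroms: sel.length ? sel : null};
}
function setFilter(id, value) {
  document.getElementById(id).value = value;
  render();
}
function clearFilters() {
  for (const id of ["f-variant","f-sample","f-nvar-lo","f-nvar-hi",
                    "f-size-lo","f-size-hi"])
    document.getElementById(id).value = "";
  for (const o of document.getElementById("f-chroms").options)
    o.selected = false;
  render();
}
function showImage(r) {
  document.getElementById("image-panel").innerHTML =
    "<h3>" + r.sample_id + " " + r.chrom + ":" + r.start + "-" + r.end +
    "</h3><img src=\\"" + r.image_path + "\\">";
}
function render() {
  const f = currentFilters();
  const body = document.querySelector("#event-table tbody");
  body.innerHTML = "";
  let shown = 0;
  for (const r of ROWS) {
    if (!rowPasses(r, f)) continue;
    shown += 1;
    const tr = document.createElement("tr");
    const cells = [r.chrom, r.start, r.end, r.region_size,
                   r.variant_ids.join(", "), r.n_variants, r.sample_id];
    cells.forEach((c, i) => {
      const td = document.createElement("td");
      td.textContent = c;
      if (i === 4 && r.variant_ids.length) {
        td.className = "clickable";
        td.onclick = e => { e.stopPropagation();
                            setFilter("f-variant", r.variant_ids[0]); };
      } else if (i === 5) {
        td.className = "clickable";
        td.onclick = e => { e.stopPropagation();
                            setFilter("f-nvar-lo", r.n_variants);
                            setFilter("f-nvar-hi", r.n_variants); };
      } else if (i === 6) {
        td.className = "clickable";
        td.onclick = e => { e.stopPropagation();
                            setFilter("f-sample", r.sample_id); };
      }
      tr.appendChild(td);
    });
    tr.onclick = () => showImage(r);
    body.appendChild(tr);
  }
  document.getElementById("count").textContent =
    shown + " of " + ROWS.length + " events shown";
}
const chromSel = document.getElementById("f-chroms");
for (const c of [...new Set(ROWS.flatMap(r => r.chroms))]) {
  const o = document.createElement("option");
  o.value = c; o.textContent = c;
  chromSel.appendChild(o);
}
chromSel.onchange = render;
for (const id of ["f-variant","f-sample","f-nvar-lo","f-nvar-hi",
                  "f-size-lo","f-size-hi"])
  document.getElementById(id).oninput = render;
render();
</script>
</body>
</html>
"""


def emit_viewer(rows, out_path, title: str = "Structural variant events") -> str:
    """Write the single-file HTML viewer; image links are relative paths."""
    payload = json.dumps([asdict(r) for r in rows], sort_keys=True)
    page = _PAGE.replace("__TITLE__", html.escape(title)).replace(
        "__ROWS__", payload)
    with open(out_path, "w") as fh:
        fh.write(page)
    return str(out_path)
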