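"""Block-diagram rendering of rearrangement networks.

Each event is drawn with the reference on the x axis (one panel per
chromosome, left-to-right in contig order) and the sample haplotype as rows,
top-to-bottom in sample order.  A row's filled segment spans its block's
reference extent; row thickness scales with alignment support (saturating),
inverted blocks carry a direction marker, dotted lines join blocks that are
adjacent in the sample, and deleted blocks appear on the reference axis only.
A chain track beneath the panel lists block labels in reference order and
then in sample order with a prime mark on inverted blocks.  SVG output is
byte-deterministic for fixed input.
"""

from __future__ import annotations

import logging

import matplotlib
from matplotlib.figure import Figure
from matplotlib import patches

from .formats_io import read_bed
from .model import (
    INVERTED,
    PlotSpec,
    SVNetwork,
    contig_sort_key,
)

log = logging.getLogger(__name__)

_PANEL_GAP = 0.02
_MIN_PANEL_FRAC = 0.12
_BLOCK_COLOR = "#2b3a67"
_INV_COLOR = "#a63d40"
_REF_COLOR = "#8d99ae"


class GenomeXMapper:
    """Map (chrom, position) to figure x in [0, 1] across per-chrom panels."""

    def __init__(self, region: dict, contig_order=None):
        chroms = sorted(region, key=lambda c: contig_sort_key(c, contig_order))
        spans = {c: max(1, region[c][1] - region[c][0]) for c in chroms}
        total = sum(spans.values())
        fracs = {c: max(_MIN_PANEL_FRAC, spans[c] / total) for c in chroms}
        norm = sum(fracs.values()) + _PANEL_GAP * (len(chroms) - 1)
        self.panels = {}
        x = 0.0
        for chrom in chroms:
            width = fracs[chrom] / norm
            self.panels[chrom] = (x, width, region[chrom])
            x += width + _PANEL_GAP / norm

    def x(self, chrom: str, pos: int) -> float:
        x0, width, (lo, hi) = self.panels[chrom]
        return x0 + width * (pos - lo) / max(1, hi - lo)


def event_image_name(net: SVNetwork, ext: str, contig_order=None) -> str:
    parts = [
        f"{chrom}-{net.region[chrom][0]}-{net.region[chrom][1]}"
        for chrom in net.chroms(contig_order)
    ]
    return f"{net.sample_id}_{'__'.join(parts)}.{ext}"


def chain_strings(net: SVNetwork):
    """(reference order, sample order) label strings; ' marks inversion."""
    ref_blocks = sorted(
        {(b.chrom, b.start, b.label) for b in net.blocks},
        key=lambda t: (contig_sort_key(t[0]), t[1]),
    )
    ref = " ".join(label for _, _, label in ref_blocks)
    sample = " ".join(
        b.label + ("'" if b.orientation == INVERTED else "")
        for b in net.sample_blocks()
    )
    return ref, sample


def clip_annotations(intervals, region: dict):
    """Clip (chrom, start, end, name) intervals to the event window."""
    out = []
    for chrom, start, end, name in intervals:
        if chrom not in region:
            continue
        lo, hi = region[chrom]
        cs, ce = max(start, lo), min(end, hi)
        if cs < ce:
            out.append((chrom, cs, ce, name))
    return out


def render_annotations(tracks, region: dict):
    """Load and clip BED annotation tracks to the event window."""
    return [(name, clip_annotations(read_bed(path), region))
            for name, path in tracks]


def _sample_endpoint_x(mapper, blk, which: str) -> float:
    # sample-orientation start/end of a block in figure coordinates
    if (which == "end") == (blk.orientation != INVERTED):
        return mapper.x(blk.chrom, blk.end)
    return mapper.x(blk.chrom, blk.start)


def render_network(net: SVNetwork, spec: PlotSpec, out_path,
                   contig_order=None) -> str:
    """Render one network to ``out_path``; returns the path written."""
    unique_blocks = sorted(
        {(b.chrom, b.start, b.end, b.label) for b in net.blocks},
        key=lambda t: (contig_sort_key(t[0], contig_order), t[1]),
    )
    if not unique_blocks:
        raise ValueError("cannot render a network with no blocks")
    mapper = GenomeXMapper(net.region, contig_order)
    rows = net.sample_blocks()
    ann_tracks = render_annotations(spec.annotation_tracks, net.region)

    n_rows = max(1, len(rows))
    fig_height = 1.8 + 0.4 * n_rows + 0.5 * len(ann_tracks)
    fig = Figure(figsize=(10, fig_height))
    ax = fig.add_axes([0.04, 0.05, 0.92, 0.9])
    ax.set_xlim(0, 1)
    y_ref = 1.0
    y_chain = -(n_rows + 1.2)
    y_bottom = y_chain - 1.0 - 1.0 * len(ann_tracks)
    ax.set_ylim(y_bottom, y_ref + 1.2)
    ax.axis("off")

    # reference track
    for chrom, start, end, label in unique_blocks:
        x0, x1 = mapper.x(chrom, start), mapper.x(chrom, end)
        ax.add_patch(patches.Rectangle(
            (x0, y_ref), x1 - x0, 0.45, facecolor="none",
            edgecolor=_REF_COLOR, linewidth=1.0,
        ))
        if spec.show_labels:
            ax.text((x0 + x1) / 2, y_ref + 0.55, label, ha="center",
                    va="bottom", fontsize=8, color="#333333")
    for chrom, (x0, width, (lo, hi)) in sorted(mapper.panels.items()):
        if spec.show_labels:
            ax.text(x0 + width / 2, y_ref + 1.0, f"{chrom}:{lo:,}-{hi:,}",
                    ha="center", va="bottom", fontsize=8, color="#555555")

    # sample rows
    dashed = not net.resolved
    for blk in rows:
        y = -blk.sample_order_index - 0.5
        x0 = mapper.x(blk.chrom, blk.start)
        x1 = mapper.x(blk.chrom, blk.end)
        height = spec.thickness(blk.support)
        color = _INV_COLOR if blk.orientation == INVERTED else _BLOCK_COLOR
        ax.add_patch(patches.Rectangle(
            (x0, y - height / 2), x1 - x0, height, facecolor=color,
            edgecolor=color, linewidth=0.8,
            linestyle="--" if dashed else "-",
        ))
        if blk.orientation == INVERTED and spec.show_labels:
            ax.annotate("", xy=(x0, y), xytext=(x1, y),
                        arrowprops={"arrowstyle": "->", "color": "white", "lw": 1.2})
    for prev, nxt in zip(rows, rows[1:]):
        ax.plot(
            [_sample_endpoint_x(mapper, prev, "end"),
             _sample_endpoint_x(mapper, nxt, "start")],
            [-prev.sample_order_index - 0.5, -nxt.sample_order_index - 0.5],
            linestyle=":", color="#555555", linewidth=1.0,
        )
    if not rows:
        ax.text(0.5, -0.5, "no ordered sample blocks", ha="center",
                fontsize=9, color="#888888")
    if not net.resolved:
        ax.text(0.5, y_ref + 1.05, "incompletely resolved structure",
                ha="center", va="bottom", fontsize=10, color=_INV_COLOR,
                fontweight="bold")

    # chain track
    ref_chain, sample_chain = chain_strings(net)
    ax.text(0.0, y_chain, f"reference: {ref_chain}", fontsize=9,
            family="monospace", va="center")
    ax.text(0.0, y_chain - 0.7, f"sample:    {sample_chain}", fontsize=9,
            family="monospace", va="center")

    # annotation tracks
    for t, (name, intervals) in enumerate(ann_tracks):
        y = y_chain - 1.6 - 1.0 * t
        ax.text(0.0, y + 0.35, name, fontsize=8, color="#555555")
        for chrom, start, end, label in intervals:
            x0, x1 = mapper.x(chrom, start), mapper.x(chrom, end)
            ax.add_patch(patches.Rectangle(
                (x0, y - 0.15), x1 - x0, 0.3, facecolor="#6a994e",
                edgecolor="none",
            ))
            if spec.show_labels and label:
                ax.text((x0 + x1) / 2, y - 0.25, label, ha="center",
                        va="top", fontsize=7, color="#333333")

    with matplotlib.rc_context({"svg.hashsalt": "svblocks"}):
        if spec.image_format == "svg":
            fig.savefig(str(out_path), format="svg", metadata={"Date": None})
        else:
            fig.savefig(str(out_path), format=spec.image_format, dpi=spec.dpi)
    return str(out_path)
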