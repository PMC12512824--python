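"""Stage orchestration: extract -> plot -> viewer.

``run_extract`` executes the full reconstruction (parse VCF, extract breaks,
collect evidence, connect, build networks, order blocks, count support,
coverage filter) and writes the per-sample JSON and BED.  ``run_plot``
renders one image per retained event, applying the optional simple-network
filter at plot time, and ``run_viewer`` builds the merged HTML index over one
or more samples.  All stages are deterministic for fixed inputs and seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pysam

from . import __version__, breakgraph, filters, formats_io, plotting, viewer
from .model import FilterConfig, PlotSpec, SVNetwork

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    bam: str = ""
    vcf: str = ""
    sample_id: str = "sample"
    out_dir: str = "."
    tolerance: int = breakgraph.DEFAULT_TOL
    min_clip: int = breakgraph.DEFAULT_MIN_CLIP
    merge_window: int = 10
    fetch_window: int = 1000
    phase_gap_limit: int = breakgraph.DEFAULT_PHASE_GAP_LIMIT
    margin_frac: float = breakgraph.DEFAULT_MARGIN_FRAC
    filter: FilterConfig = field(default_factory=FilterConfig)
    plot: PlotSpec = field(default_factory=PlotSpec)
    seed: int = 0
    reference: str = None

    def echo(self) -> dict:
        return asdict(self)


def contig_order_from_bam(bam_path, reference=None) -> dict:
    with pysam.AlignmentFile(str(bam_path), reference_filename=reference) as af:
        return {name: i for i, name in enumerate(af.references)}


def _single_ended_networks(calls, cfg) -> list:
    nets = []
    for call in calls:
        if not call.single_ended:
            continue
        brk = formats_io.call_breaks(call)[0]
        net = SVNetwork(breaks=[brk], resolved=False,
                        variant_ids=[call.id], sample_id=cfg.sample_id)
        net.region = breakgraph.event_region([brk], cfg.margin_frac)
        net.blocks = breakgraph.partition_blocks([brk], net.region)
        net.filters = []
        nets.append(net)
    return nets


def run_extract(cfg: RunConfig):
    """Full reconstruction; returns (json_path, bed_path)."""
    for path in (cfg.bam, cfg.vcf):
        if not os.path.exists(str(path)):
            raise FileNotFoundError(path)
    os.makedirs(cfg.out_dir, exist_ok=True)
    log.info("effective configuration: %s", json.dumps(cfg.echo(), default=str))

    calls = formats_io.parse_sv_vcf(cfg.vcf, cfg.sample_id)
    breaks = formats_io.extract_breaks(calls, cfg.merge_window)
    contig_order = contig_order_from_bam(cfg.bam, cfg.reference)
    evidence = formats_io.collect_alignment_evidence(
        cfg.bam, [b for b in breaks if b.chrom in contig_order],
        window=cfg.fetch_window, reference=cfg.reference,
    )
    connections = breakgraph.connect_breaks(
        breaks, evidence, tol=cfg.tolerance, min_clip=cfg.min_clip,
        phase_gap_limit=cfg.phase_gap_limit,
    )
    nets = breakgraph.build_networks(connections, contig_order)
    matched = {b for c in connections for b in (c.break_1, c.break_2)}
    log.info("stage counts: %d calls, %d breaks (%d skipped), %d connections, "
             "%d networks", len(calls), len(breaks), len(breaks) - len(matched),
             len(connections), len(nets))

    call_map = formats_io.assign_call_breaks(calls, breaks, cfg.merge_window)
    break_to_calls = {}
    for call_id, brks in call_map.items():
        for brk in brks:
            break_to_calls.setdefault(brk, set()).add(call_id)

    background = filters.median_background_depth(
        cfg.bam, seed=cfg.seed, reference=cfg.reference)
    for net in nets:
        net.sample_id = cfg.sample_id
        breakgraph.order_blocks(net, evidence, block_cap=cfg.filter.block_cap,
                                margin_frac=cfg.margin_frac,
                                contig_order=contig_order)
        breakgraph.count_support(net, evidence, tol=cfg.tolerance,
                                 min_clip=cfg.min_clip)
        net.variant_ids = sorted(
            {cid for brk in net.breaks for cid in break_to_calls.get(brk, ())}
        )
        filters.apply_filters(net, cfg.bam, cfg.filter, seed=cfg.seed,
                              reference=cfg.reference,
                              background_depth=background)
    nets.extend(_single_ended_networks(calls, cfg))

    doc = formats_io.JsonDocument(sample_id=cfg.sample_id, events=nets,
                                  version=__version__)
    json_path = os.path.join(cfg.out_dir, f"{cfg.sample_id}_events.json")
    bed_path = os.path.join(cfg.out_dir, f"{cfg.sample_id}_events.bed")
    formats_io.write_json(doc, json_path)
    formats_io.write_event_bed(doc, bed_path)
    resolved = sum(net.resolved for net in nets)
    log.info("wrote %d events (%d resolved) to %s", len(nets), resolved, json_path)
    return json_path, bed_path


def retained_events(doc, cfg: RunConfig):
    """Events that pass the recorded filters plus the simple-network filter."""
    out = []
    for net in doc.events:
        if net.filters:
            continue
        keep, reason = filters.simple_network_filter(net, cfg.filter)
        if not keep:
            log.debug("event %s suppressed at plot time: %s",
                      sorted(net.region), reason)
            continue
        out.append(net)
    return out


def run_plot(cfg: RunConfig, json_paths, image_dir=None) -> list:
    """Render one image per retained event; returns image paths."""
    image_dir = image_dir or os.path.join(cfg.out_dir, "images")
    os.makedirs(image_dir, exist_ok=True)
    contig_order = (contig_order_from_bam(cfg.bam, cfg.reference)
                    if cfg.bam and os.path.exists(str(cfg.bam)) else None)
    written = []
    for json_path in json_paths:
        doc = formats_io.read_json(json_path)
        for net in retained_events(doc, cfg):
            name = plotting.event_image_name(net, cfg.plot.image_format,
                                             contig_order)
            written.append(plotting.render_network(
                net, cfg.plot, os.path.join(image_dir, name), contig_order))
    log.info("rendered %d images to %s", len(written), image_dir)
    return written


def run_viewer(cfg: RunConfig, json_paths, image_dir=None, out_html=None) -> str:
    """Build the merged HTML viewer (plus a TSV index) over rendered images."""
    image_dir = image_dir or os.path.join(cfg.out_dir, "images")
    out_html = out_html or os.path.join(image_dir, "index.html")
    docs = [formats_io.read_json(p) for p in json_paths]
    for doc in docs:
        doc.events = retained_events(doc, cfg)
    rows = viewer.build_index(docs, image_dir,
                              image_ext=cfg.plot.image_format)
    viewer.emit_viewer(rows, out_html)
    viewer.write_index_tsv(rows, os.path.splitext(out_html)[0] + ".tsv")
    log.info("viewer with %d rows at %s", len(rows), out_html)
    return out_html
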