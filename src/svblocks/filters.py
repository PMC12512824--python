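"""Region-reliability and simple-event filters.

Two pruning stages: (1) networks in regions with abnormal depth or pervasive
low mapping quality are dropped before output, since both are signatures of
repeats and alignment artifacts; (2) at plot time, "simple" networks -- one
or two same-chromosome forward-oriented breaks with no inverted block -- are
suppressed by default so review focuses on genuinely complex events.  Every
drop decision carries a machine-readable reason that survives in the JSON.
"""

from __future__ import annotations

import logging

import numpy as np
import pysam

from .model import INVERTED, FilterConfig, SVNetwork

log = logging.getLogger(__name__)

REASON_COVERAGE = "abnormal_coverage"
REASON_LOW_MAPQ = "low_mapping_quality"
REASON_SIMPLE = "simple_network"
REASON_SINGLE_ENDED = "single_ended_bnd"
REASON_MISSING_CONTIG = "contig_missing_from_alignments"


def _mean_depth(af, chrom, start, end) -> float:
    cov = af.count_coverage(chrom, start, end, quality_threshold=0)
    return float(sum(np.sum(c) for c in cov)) / max(1, end - start)


def median_background_depth(bam_path, window: int = 500, n_windows: int = 200,
                            seed: int = 0, reference=None) -> float:
    """Median depth over seeded random windows, zero-coverage windows excluded.

    Sampling fixed-width windows instead of a full traversal keeps the
    estimate cheap; excluding empty windows makes it a covered-genome median,
    robust to sparse or targeted alignments.
    """
    rng = np.random.default_rng(seed)
    depths = []
    with pysam.AlignmentFile(str(bam_path), reference_filename=reference) as af:
        lengths = dict(zip(af.references, af.lengths))
        contigs = sorted(lengths)
        total = sum(lengths.values())
        for _ in range(n_windows):
            offset = int(rng.integers(0, max(1, total - window)))
            for chrom in contigs:
                if offset < lengths[chrom]:
                    break
                offset -= lengths[chrom]
            end = min(offset + window, lengths[chrom])
            if end <= offset:
                continue
            depth = _mean_depth(af, chrom, offset, end)
            if depth > 0:
                depths.append(depth)
    return float(np.median(depths)) if depths else 0.0


def coverage_repeat_filter(net: SVNetwork, bam_path, cfg: FilterConfig,
                           seed: int = 0, reference=None,
                           background_depth: float = None):
    """(keep, reason) for the depth / mapping-quality reliability filter.

    Drops the network when any block's mean depth deviates from the sample
    background by more than ``coverage_fold_limit`` in either direction, or
    when the fraction of overlapping alignments below ``mapq_floor`` exceeds
    ``low_mapq_fraction_limit``.
    """
    if background_depth is None:
        background_depth = median_background_depth(bam_path, seed=seed,
                                                   reference=reference)
    unique_blocks = {(b.chrom, b.start, b.end) for b in net.blocks}
    with pysam.AlignmentFile(str(bam_path), reference_filename=reference) as af:
        valid = set(af.references)
        for chrom, start, end in sorted(unique_blocks):
            if chrom not in valid:
                return False, f"{REASON_MISSING_CONTIG}:{chrom}"
            depth = _mean_depth(af, chrom, start, end)
            if background_depth > 0:
                fold = depth / background_depth
                if fold > cfg.coverage_fold_limit or fold < 1.0 / cfg.coverage_fold_limit:
                    return False, (
                        f"{REASON_COVERAGE}:{chrom}:{start}-{end}:"
                        f"{fold:.2f}x_background"
                    )
        low = total = 0
        for chrom, (start, end) in sorted(net.region.items()):
            if chrom not in valid:
                return False, f"{REASON_MISSING_CONTIG}:{chrom}"
            for rec in af.fetch(chrom, start, end):
                if rec.is_unmapped or rec.is_secondary:
                    continue
                total += 1
                if rec.mapping_quality < cfg.mapq_floor:
                    low += 1
        if total and low / total > cfg.low_mapq_fraction_limit:
            return False, f"{REASON_LOW_MAPQ}:{low / total:.2f}_below_mapq{cfg.mapq_floor}"
    return True, None


def simple_network_filter(net: SVNetwork, cfg: FilterConfig):
    """(keep, reason) for the optional simple-event filter.

    A network is simple when its breaks lie on one chromosome, number at most
    two distinct positions, and no inverted block appears; single-ended
    unresolved breakends are also dropped.  With ``keep_simple`` set the
    filter keeps everything.
    """
    if cfg.keep_simple:
        return True, None
    if not net.connections:
        return False, REASON_SINGLE_ENDED
    chroms = {b.chrom for b in net.breaks}
    positions = {(b.chrom, b.pos) for b in net.breaks}
    has_inverted = any(b.orientation == INVERTED for b in net.blocks) or any(
        c.inverted for c in net.connections
    )
    if len(chroms) == 1 and len(positions) <= 2 and not has_inverted:
        return False, REASON_SIMPLE
    return True, None


def apply_filters(net: SVNetwork, bam_path, cfg: FilterConfig, seed: int = 0,
                  reference=None, background_depth: float = None) -> SVNetwork:
    """Record coverage/mapq drop reasons on the network (mutates, returns)."""
    keep, reason = coverage_repeat_filter(
        net, bam_path, cfg, seed=seed, reference=reference,
        background_depth=background_depth,
    )
    if not keep:
        net.filters.append(reason)
        log.info("network at %s filtered: %s", dict(net.region), reason)
    return net
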