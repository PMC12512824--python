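"""Assemble breakpoint graphs and reconstruct sample-order blocks.

The sample haplotype is modelled as an alternation of reference walks and
novel-adjacency jumps.  Split reads provide the jumps: each adjacent pair of
segments in a read's chain is a candidate junction between two break sides.
Breaks with no clipped alignment nearby are skipped.  Connected components of
the break/connection graph are rearrangement networks; within each network a
backtracking traversal that must consume every junction exactly once, with a
strictly positive-length reference walk between consecutive junctions,
recovers the order and orientation of the genomic blocks on the sample
haplotype.  The traversal starts where reads enter the event from
reference-consistent flanking sequence (the start break); ties go to the
lowest contig-order coordinate, and a network admitting zero or multiple
complete traversals is reported unresolved rather than guessed.
"""

from __future__ import annotations

import logging

from .model import (
    FORWARD,
    INVERTED,
    SIDE_LEFT,
    SIDE_RIGHT,
    Break,
    Connection,
    GenomicBlock,
    SVNetwork,
    block_labels,
    contig_sort_key,
)

log = logging.getLogger(__name__)

DEFAULT_TOL = 10
DEFAULT_MIN_CLIP = 50
DEFAULT_PHASE_GAP_LIMIT = 500_000
DEFAULT_BLOCK_CAP = 20
DEFAULT_MARGIN_FRAC = 0.10
MIN_MARGIN = 100
MAX_EXPANSIONS = 20_000


# ---------------------------------------------------------------------------
# clip-to-break matching


def _segment_boundaries(seg):
    """Clipped boundaries of a segment as (ref_coord, side, clip_len)."""
    return (
        (seg.ref_start, SIDE_RIGHT, seg.clip_left),
        (seg.ref_end, SIDE_LEFT, seg.clip_right),
    )


def match_alignment_to_break(ev, brk: Break, tol: int = DEFAULT_TOL,
                             min_clip: int = DEFAULT_MIN_CLIP) -> bool:
    """True iff some segment of ``ev`` has significant soft-clipping whose
    reference coordinate lies within ``tol`` bp of the break."""
    if tol < 0 or min_clip <= 0:
        raise ValueError("tol must be >= 0 and min_clip > 0")
    for seg in ev.segments:
        if seg.chrom != brk.chrom:
            continue
        for coord, side, clip in _segment_boundaries(seg):
            if clip >= min_clip and side == brk.side and abs(coord - brk.pos) <= tol:
                return True
    return False


def _nearest_break(index, chrom, pos, side, tol):
    candidates = index.get((chrom, side))
    if not candidates:
        return None
    best = min(candidates, key=lambda b: (abs(b.pos - pos), b.pos))
    return best if abs(best.pos - pos) <= tol else None


def _exit_point(seg):
    """Where the read leaves this segment (toward the next one)."""
    if seg.strand == "+":
        return seg.ref_end, SIDE_LEFT, seg.clip_right
    return seg.ref_start, SIDE_RIGHT, seg.clip_left


def _entry_point(seg):
    """Where the read enters this segment (from the previous one)."""
    if seg.strand == "+":
        return seg.ref_start, SIDE_RIGHT, seg.clip_left
    return seg.ref_end, SIDE_LEFT, seg.clip_right


# ---------------------------------------------------------------------------
# connections


class UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        parent = self.parent
        parent.setdefault(x, x)
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def connect_breaks(breaks, evidence, tol: int = DEFAULT_TOL,
                   min_clip: int = DEFAULT_MIN_CLIP,
                   phase_gap_limit: int = DEFAULT_PHASE_GAP_LIMIT) -> list:
    """Link breaks using split-read junctions and phase-block co-occurrence.

    Returns spanned junction connections (novel adjacencies crossed by
    reads), spanned reference adjacencies (the segment between two junctions
    of one read), and phased connections between reference-adjacent breaks of
    different read-spanned components that share an HP/PS assignment.
    Breaks with no matching alignment are dropped (skip rule).
    """
    index = {}
    for brk in breaks:
        index.setdefault((brk.chrom, brk.side), []).append(brk)

    matched_reads = {}  # Break -> set(read name)
    phased_reads = {}  # Break -> {(ps, hp): set(read name)}
    junctions = {}  # (b1, b2, inverted) -> set(read name)
    adjacencies = {}  # (b1, b2) -> set(read name)

    for ev in evidence:
        for brk in breaks:
            if match_alignment_to_break(ev, brk, tol, min_clip):
                matched_reads.setdefault(brk, set()).add(ev.read_name)
                if ev.haplotype is not None and ev.phase_set is not None:
                    phased_reads.setdefault(brk, {}).setdefault(
                        (ev.phase_set, ev.haplotype), set()
                    ).add(ev.read_name)

        pair_hits = []  # (exit break, entry break) per junction crossed, read order
        for s1, s2 in zip(ev.segments, ev.segments[1:]):
            xc, xs, xclip = _exit_point(s1)
            ec, es, eclip = _entry_point(s2)
            if xclip < min_clip or eclip < min_clip:
                continue
            b1 = _nearest_break(index, s1.chrom, xc, xs, tol)
            b2 = _nearest_break(index, s2.chrom, ec, es, tol)
            if b1 is None or b2 is None or b1 == b2:
                continue
            inverted = s1.strand != s2.strand
            key = (min(b1, b2), max(b1, b2), inverted)
            junctions.setdefault(key, set()).add(ev.read_name)
            pair_hits.append((b1, b2))
        for (_, entry_prev), (exit_next, _) in zip(pair_hits, pair_hits[1:]):
            if entry_prev != exit_next:
                key = (min(entry_prev, exit_next), max(entry_prev, exit_next))
                adjacencies.setdefault(key, set()).add(ev.read_name)

    connections = []
    uf = UnionFind()
    for (b1, b2, inverted), reads in sorted(
        junctions.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        connections.append(Connection(
            break_1=b1, break_2=b2, kind="spanned", inverted=inverted,
            support=len(reads), is_junction=True, read_names=frozenset(reads),
        ))
        uf.union(b1, b2)
    for (b1, b2), reads in sorted(adjacencies.items()):
        connections.append(Connection(
            break_1=b1, break_2=b2, kind="spanned", inverted=False,
            support=len(reads), is_junction=False, read_names=frozenset(reads),
        ))
        uf.union(b1, b2)

    connections.extend(
        _phase_connections(matched_reads, phased_reads, uf, phase_gap_limit)
    )
    return connections


def _phase_connections(matched_reads, phased_reads, uf, gap_limit):
    """Phased links between reference-adjacent breaks of distinct components."""
    out = []
    matched = sorted(matched_reads)
    for b1, b2 in zip(matched, matched[1:]):
        if b1.chrom != b2.chrom or b2.pos - b1.pos > gap_limit:
            continue
        if uf.find(b1) == uf.find(b2):
            continue
        sets1 = phased_reads.get(b1, {})
        sets2 = phased_reads.get(b2, {})
        shared = sorted(set(sets1) & set(sets2))
        if not shared:
            continue
        key = max(shared, key=lambda k: min(len(sets1[k]), len(sets2[k])))
        support = min(len(sets1[key]), len(sets2[key]))
        if support < 1:
            continue
        out.append(Connection(
            break_1=b1, break_2=b2, kind="phased", inverted=False,
            support=support, phase_set=key[0], is_junction=False,
            read_names=frozenset(sets1[key] | sets2[key]),
        ))
        uf.union(b1, b2)
    return out


# ---------------------------------------------------------------------------
# networks


def build_networks(connections, contig_order=None) -> list:
    """Group connections into connected components, one network each."""
    uf = UnionFind()
    for conn in connections:
        uf.union(conn.break_1, conn.break_2)
    groups = {}
    for conn in connections:
        groups.setdefault(uf.find(conn.break_1), []).append(conn)
    nets = []
    for conns in groups.values():
        breaks = sorted({b for c in conns for b in (c.break_1, c.break_2)})
        nets.append(SVNetwork(
            breaks=breaks,
            connections=sorted(conns, key=lambda c: (c.break_1, c.break_2, c.kind)),
        ))
    nets.sort(key=lambda n: (contig_sort_key(n.breaks[0].chrom, contig_order),
                             n.breaks[0].pos, n.breaks[0].side))
    return nets


def event_region(breaks, margin_frac: float = DEFAULT_MARGIN_FRAC,
                 min_margin: int = MIN_MARGIN) -> dict:
    """Per-chromosome plot/analysis window: break span plus flanking margins."""
    region = {}
    by_chrom = {}
    for brk in breaks:
        by_chrom.setdefault(brk.chrom, []).append(brk.pos)
    for chrom, positions in by_chrom.items():
        lo, hi = min(positions), max(positions)
        margin = max(min_margin, int(round(margin_frac * (hi - lo))))
        region[chrom] = (max(0, lo - margin), hi + margin)
    return region


def partition_blocks(breaks, region, contig_order=None) -> list:
    """Reference blocks between adjacent break positions, labelled A, B, ..."""
    blocks = []
    for chrom in sorted(region, key=lambda c: contig_sort_key(c, contig_order)):
        start, end = region[chrom]
        cuts = sorted({b.pos for b in breaks if b.chrom == chrom and start < b.pos < end})
        edges = [start] + cuts + [end]
        for lo, hi in zip(edges, edges[1:]):
            blocks.append(GenomicBlock(chrom=chrom, start=lo, end=hi))
    for label, blk in zip(block_labels(len(blocks)), blocks):
        blk.label = label
    return blocks


# ---------------------------------------------------------------------------
# traversal


class _Traverser:
    """Enumerate complete haplotype traversals of a network's junctions."""

    def __init__(self, junctions, region, max_expansions=MAX_EXPANSIONS):
        self.junctions = junctions
        self.region = region
        self.max_expansions = max_expansions
        self.expansions = 0
        self.exhausted = False

    def complete_from(self, start: Break, limit: int = 2) -> list:
        """Complete traversals whose first junction exit is ``start``."""
        results = []
        region_start = self.region[start.chrom][0]
        if start.pos <= region_start:
            return results
        for ji, junction in enumerate(self.junctions):
            for end in (junction.break_1, junction.break_2):
                if end != start:
                    continue
                other = junction.break_2 if end is junction.break_1 else junction.break_1
                walk = (start.chrom, region_start, start.pos, 1)
                state = self._landing(other)
                used = frozenset([ji])
                self._dfs(state, used, [walk], results, limit)
                if len(results) >= limit:
                    return results
        return results

    @staticmethod
    def _landing(brk: Break):
        direction = 1 if brk.side == SIDE_RIGHT else -1
        return (brk.chrom, brk.pos, direction)

    def _dfs(self, state, used, walks, results, limit):
        if len(results) >= limit or self.exhausted:
            return
        self.expansions += 1
        if self.expansions > self.max_expansions:
            self.exhausted = True
            return
        chrom, pos, direction = state
        if len(used) == len(self.junctions):
            if direction == 1 and chrom in self.region:
                final = (chrom, pos, self.region[chrom][1], 1)
                results.append(walks + [final])
            return
        for ji, junction in enumerate(self.junctions):
            if ji in used:
                continue
            for end in (junction.break_1, junction.break_2):
                if end.chrom != chrom:
                    continue
                if direction == 1 and end.side == SIDE_LEFT and end.pos > pos:
                    walk = (chrom, pos, end.pos, 1)
                elif direction == -1 and end.side == SIDE_RIGHT and end.pos < pos:
                    walk = (chrom, end.pos, pos, -1)
                else:
                    continue
                other = junction.break_2 if end is junction.break_1 else junction.break_1
                self._dfs(self._landing(other), used | {ji}, walks + [walk],
                          results, limit)


def _flank_entered(evidence, tol, min_clip):
    """Left-side break coordinates where reads enter from reference flank.

    A candidate start break must be reachable from reference-consistent
    sequence: some read's *first* segment, with an essentially unclipped read
    start, is clipped at the candidate coordinate.  Returns a set of
    (chrom, coordinate) pairs (coordinates unrounded; caller matches +/-tol).
    """
    coords = set()
    for ev in evidence:
        seg = ev.segments[0]
        start_clip = seg.clip_left if seg.strand == "+" else seg.clip_right
        if start_clip >= min_clip:
            continue
        coord, side, clip = _exit_point(seg)
        if side == SIDE_LEFT and clip >= min_clip:
            coords.add((seg.chrom, coord))
    return coords


def _traverse(net: SVNetwork, evidence=None, contig_order=None,
              tol=DEFAULT_TOL, min_clip=DEFAULT_MIN_CLIP):
    """(start break, walks) for the unique complete traversal, else (None, None)."""
    junctions = [c for c in net.connections if c.is_junction]
    if not junctions:
        return None, None
    traverser = _Traverser(junctions, net.region)
    candidates = sorted(
        {e for c in junctions for e in (c.break_1, c.break_2)
         if e.side == SIDE_LEFT and e.chrom in net.region},
        key=lambda b: (contig_sort_key(b.chrom, contig_order), b.pos),
    )
    if evidence is not None:
        entered = _flank_entered(evidence, tol, min_clip)
        candidates = [
            b for b in candidates
            if any(c == b.chrom and abs(pos - b.pos) <= tol for c, pos in entered)
        ]
    for candidate in candidates:
        results = traverser.complete_from(candidate, limit=2)
        if traverser.exhausted:
            log.warning("traversal search budget exhausted; network unresolved")
            return None, None
        if len(results) == 1:
            return candidate, results[0]
        if len(results) > 1:
            log.info("ambiguous traversal from %s; network unresolved", candidate)
            return None, None
    return None, None


def find_start_break(net: SVNetwork, evidence=None, contig_order=None,
                     margin_frac: float = DEFAULT_MARGIN_FRAC):
    """Break where reads enter the event from reference-consistent flank.

    Defined as the lowest (contig order, coordinate) junction exit from which
    a unique complete traversal of all junctions exists; ``None`` when no
    such unambiguous entry exists.
    """
    if not net.region:
        net.region = event_region(net.breaks, margin_frac)
    start, _ = _traverse(net, evidence, contig_order)
    return start


def order_blocks(net: SVNetwork, evidence=None, block_cap: int = DEFAULT_BLOCK_CAP,
                 margin_frac: float = DEFAULT_MARGIN_FRAC,
                 contig_order=None) -> SVNetwork:
    """Populate ``net.blocks`` with reference partition and sample ordering.

    Mutates and returns ``net``.  Networks whose reference partition exceeds
    ``block_cap`` blocks, or that admit no unique complete traversal, are
    marked unresolved and keep the partition as a partial (axis-only) result.
    """
    net.region = event_region(net.breaks, margin_frac)
    base = partition_blocks(net.breaks, net.region, contig_order)
    if len(base) > block_cap:
        log.info("network exceeds block cap (%d > %d); unresolved",
                 len(base), block_cap)
        net.blocks = base
        net.resolved = False
        net.start_break = None
        return net

    start, walks = _traverse(net, evidence, contig_order)
    if walks is None:
        net.blocks = base
        net.resolved = False
        net.start_break = None
        return net

    by_chrom = {}
    for blk in base:
        by_chrom.setdefault(blk.chrom, []).append(blk)
    visited = []
    idx = 0
    seen = {}
    for chrom, lo, hi, direction in walks:
        covered = [b for b in by_chrom.get(chrom, ())
                   if b.start >= lo and b.end <= hi]
        if direction == -1:
            covered = covered[::-1]
        for blk in covered:
            visited.append(GenomicBlock(
                chrom=blk.chrom, start=blk.start, end=blk.end,
                orientation=FORWARD if direction == 1 else INVERTED,
                sample_order_index=idx, label=blk.label,
            ))
            seen[id(blk)] = seen.get(id(blk), 0) + 1
            idx += 1
    unvisited = [blk for blk in base if id(blk) not in seen]
    net.blocks = visited + unvisited
    net.start_break = start
    net.resolved = True
    count_support(net)
    return net


def count_support(net: SVNetwork, evidence=None, tol: int = DEFAULT_TOL,
                  min_clip: int = DEFAULT_MIN_CLIP) -> SVNetwork:
    """Fill support counts: connections from distinct matching read names,
    blocks from the max over their bounding connections."""
    if evidence is not None:
        for conn in net.connections:
            if conn.kind == "spanned" and conn.read_names:
                conn.support = len(conn.read_names)
    boundary_support = {}
    for conn in net.connections:
        for brk in (conn.break_1, conn.break_2):
            key = (brk.chrom, brk.pos)
            boundary_support[key] = max(boundary_support.get(key, 0), conn.support)
    for blk in net.blocks:
        blk.support = max(
            boundary_support.get((blk.chrom, blk.start), 0),
            boundary_support.get((blk.chrom, blk.end), 0),
        )
    return net
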