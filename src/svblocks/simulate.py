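"""Synthetic rearrangement fixtures: phased split reads plus truth VCFs.

A :class:`RearrangementSpec` describes one sample haplotype as a reference
window that is replaced by an ordered list of oriented reference segments,
embedded in reference-consistent flanks.  From that description the module
derives, all from one seed:

* a synthetic reference (random sequence, chr-style contig names);
* coordinate-sorted, indexed BAM alignments of the variant haplotype, with
  soft-clips, SA chains, strand flips across inverted segments and HP/PS
  phasing tags, plus reference-haplotype (HP=2) reads so heterozygous depth
  signatures are realistic;
* a truth VCF of mated breakend records, one pair per junction;
* the expected reconstruction (truth network) and per-junction read support.

Defaults emulate a ~20x phased HiFi dataset per haplotype: 6 kb +/- 0.8 kb
reads, 2 bp of clip-position jitter at junctions, 10% of reads unphased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pysam

from .breakgraph import (
    DEFAULT_BLOCK_CAP,
    DEFAULT_MARGIN_FRAC,
    DEFAULT_MIN_CLIP,
    DEFAULT_TOL,
    event_region,
    partition_blocks,
)
from .model import (
    FORWARD,
    INVERTED,
    SIDE_LEFT,
    SIDE_RIGHT,
    Break,
    GenomicBlock,
    SVNetwork,
    Segment,
    natural_contig_key,
)

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SegmentSpec:
    """One oriented reference segment of the sample haplotype."""

    chrom: str
    start: int
    end: int
    orientation: str = FORWARD

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self):
        return self.end - self.start


@dataclass
class RearrangementSpec:
    """Scripted rearrangement: reference window replaced by ``blocks``.

    ``anchor_chrom:[window_start, window_end)`` is removed from the reference
    haplotype and replaced by the concatenation of ``blocks`` (possibly
    empty: a pure deletion; possibly zero-length window: an insertion site).
    ``flank`` bp of reference-consistent sequence is kept on each side.
    """

    name: str
    anchor_chrom: str
    window_start: int
    window_end: int
    blocks: tuple = ()
    flank: int = 8000
    coverage: float = 20.0
    ref_coverage: float = 20.0
    read_length: int = 6000
    read_length_sd: int = 800
    seed: int = 1
    haplotype: int = 1
    phase_set: Optional[int] = None
    jitter: int = 2
    unphased_fraction: float = 0.10
    mapq0_fraction: float = 0.0
    suppress_junctions: tuple = ()
    spike_region: Optional[tuple] = None  # (chrom, start, end)
    spike_coverage: float = 0.0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.window_start > self.window_end or self.window_start < self.flank:
            raise ValueError("invalid replacement window")
        if self.window_start == self.window_end and not self.blocks:
            raise ValueError("spec describes no rearrangement")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass(frozen=True)
class _Piece:
    chrom: str
    start: int
    end: int
    orientation: str

    @property
    def length(self):
        return self.end - self.start


@dataclass
class ReadTruth:
    name: str
    hap_start: int
    hap_end: int
    segments: list  # jittered Segment chain actually written to the BAM
    ideal_segments: list  # pre-jitter chain, for layout oracles
    haplotype: Optional[int]
    phase_set: Optional[int]


@dataclass
class SimResult:
    spec: RearrangementSpec
    bam_path: str
    vcf_path: str
    truth: SVNetwork
    junctions: list  # [(exit Break, entry Break)] in haplotype order
    junction_support: dict  # (min Break, max Break) -> expected read count
    reads: list  # list[ReadTruth] (variant haplotype only)
    pieces: list  # merged haplotype chain, list[_Piece]
    contigs: dict  # name -> length
    refseq: dict = field(default_factory=dict)  # name -> sequence


def _haplotype_chain(spec: RearrangementSpec) -> list:
    pieces = [_Piece(spec.anchor_chrom, spec.window_start - spec.flank,
                     spec.window_start, FORWARD)]
    pieces += [_Piece(b.chrom, b.start, b.end, b.orientation) for b in spec.blocks]
    pieces.append(_Piece(spec.anchor_chrom, spec.window_end,
                         spec.window_end + spec.flank, FORWARD))
    merged = [pieces[0]]
    for piece in pieces[1:]:
        prev = merged[-1]
        if (piece.chrom == prev.chrom and piece.orientation == prev.orientation
                and ((piece.orientation == FORWARD and piece.start == prev.end)
                     or (piece.orientation == INVERTED and piece.end == prev.start))):
            if piece.orientation == FORWARD:
                merged[-1] = _Piece(prev.chrom, prev.start, piece.end, FORWARD)
            else:
                merged[-1] = _Piece(prev.chrom, piece.start, prev.end, INVERTED)
        else:
            merged.append(piece)
    min_len = max(2 * 2 + 6, 4 * max(1, spec.jitter))
    for piece in merged:
        if piece.length < min_len:
            raise ValueError(
                f"{spec.name}: haplotype segment {piece} shorter than {min_len} bp; "
                "junctions too close for the read/jitter model"
            )
    return merged


def _junctions(pieces) -> list:
    out = []
    for p, q in zip(pieces, pieces[1:]):
        if p.orientation == FORWARD:
            exit_brk = Break(p.chrom, p.end, SIDE_LEFT)
        else:
            exit_brk = Break(p.chrom, p.start, SIDE_RIGHT)
        if q.orientation == FORWARD:
            entry_brk = Break(q.chrom, q.start, SIDE_RIGHT)
        else:
            entry_brk = Break(q.chrom, q.end, SIDE_LEFT)
        out.append((exit_brk, entry_brk))
    return out


def _contig_lengths(spec: RearrangementSpec, pieces) -> dict:
    needed = {}
    coords = [(spec.anchor_chrom, spec.window_end + spec.flank)]
    coords += [(p.chrom, p.end + spec.flank) for p in pieces]
    if spec.spike_region:
        coords.append((spec.spike_region[0], spec.spike_region[2]))
    for chrom, hi in coords:
        needed[chrom] = max(needed.get(chrom, 0), hi + spec.read_length + 1000)
    return dict(sorted(needed.items(), key=lambda kv: natural_contig_key(kv[0])))


def _read_to_segments(pieces, offsets, r0: int, r1: int) -> list:
    """Map a haplotype-space read interval to reference-space segments."""
    segs = []
    rlen = r1 - r0
    for piece, off in zip(pieces, offsets):
        a = max(r0, off)
        b = min(r1, off + piece.length)
        if a >= b:
            continue
        q0, q1 = a - r0, b - r0
        if piece.orientation == FORWARD:
            ref_start = piece.start + (a - off)
            ref_end = piece.start + (b - off)
            strand = "+"
            clip_left, clip_right = q0, rlen - q1
        else:
            ref_start = piece.end - (b - off)
            ref_end = piece.end - (a - off)
            strand = "-"
            clip_left, clip_right = rlen - q1, q0
        segs.append(Segment(piece.chrom, ref_start, ref_end, strand,
                            clip_left, clip_right, 60))
    return segs


def _apply_jitter(segs, rng, jitter: int, rlen: int):
    """Shift each internal segment boundary by up to +/- jitter bp."""
    if jitter == 0 or len(segs) < 2:
        return list(segs)
    out = list(segs)
    for i in range(len(out) - 1):
        delta = int(rng.integers(-jitter, jitter + 1))
        if delta == 0:
            continue
        s1, s2 = out[i], out[i + 1]
        if s1.length + delta < 2 or s2.length - delta < 2:
            continue
        if s1.strand == "+":
            s1 = Segment(s1.chrom, s1.ref_start, s1.ref_end + delta, "+",
                         s1.clip_left, s1.clip_right - delta, s1.mapq)
        else:
            s1 = Segment(s1.chrom, s1.ref_start - delta, s1.ref_end, "-",
                         s1.clip_left - delta, s1.clip_right, s1.mapq)
        if s2.strand == "+":
            s2 = Segment(s2.chrom, s2.ref_start + delta, s2.ref_end, "+",
                         s2.clip_left + delta, s2.clip_right, s2.mapq)
        else:
            s2 = Segment(s2.chrom, s2.ref_start, s2.ref_end - delta, "-",
                         s2.clip_left, s2.clip_right + delta, s2.mapq)
        out[i], out[i + 1] = s1, s2
    return out


def _exit_entry_ok(s1: Segment, s2: Segment, exit_brk: Break, entry_brk: Break,
                   tol: int, min_clip: int) -> bool:
    exit_coord = s1.ref_end if s1.strand == "+" else s1.ref_start
    entry_coord = s2.ref_start if s2.strand == "+" else s2.ref_end
    exit_clip = s1.clip_right if s1.strand == "+" else s1.clip_left
    entry_clip = s2.clip_left if s2.strand == "+" else s2.clip_right
    return (exit_clip >= min_clip and entry_clip >= min_clip
            and abs(exit_coord - exit_brk.pos) <= tol
            and abs(entry_coord - entry_brk.pos) <= tol)


def _truth_network(spec, pieces, junctions, kept_junctions,
                   block_cap=DEFAULT_BLOCK_CAP, margin_frac=DEFAULT_MARGIN_FRAC):
    kept_breaks = sorted({b for j in kept_junctions for b in j})
    if not kept_breaks:
        return SVNetwork(resolved=False)
    region = event_region(kept_breaks, margin_frac)
    base = partition_blocks(kept_breaks, region)
    net = SVNetwork(breaks=kept_breaks, region=region, sample_id=spec.name)
    if len(kept_junctions) < len(junctions) or len(base) > block_cap:
        net.blocks = base
        net.resolved = False
        return net
    by_chrom = {}
    for blk in base:
        by_chrom.setdefault(blk.chrom, []).append(blk)
    visited_ids = set()
    ordered = []
    idx = 0
    for piece in pieces:
        lo, hi = region[piece.chrom]
        lo, hi = max(lo, piece.start), min(hi, piece.end)
        covered = [b for b in by_chrom.get(piece.chrom, ())
                   if b.start >= lo and b.end <= hi]
        if piece.orientation == INVERTED:
            covered = covered[::-1]
        for blk in covered:
            ordered.append(GenomicBlock(
                chrom=blk.chrom, start=blk.start, end=blk.end,
                orientation=piece.orientation, sample_order_index=idx,
                label=blk.label,
            ))
            visited_ids.add(id(blk))
            idx += 1
    net.blocks = ordered + [b for b in base if id(b) not in visited_ids]
    net.start_break = kept_junctions[0][0]
    net.resolved = True
    return net


def simulate(spec: RearrangementSpec, out_dir) -> SimResult:
    """Generate reads, truth VCF and expected reconstruction for one spec."""
    import os

    pieces = _haplotype_chain(spec)
    junctions = _junctions(pieces)
    contigs = _contig_lengths(spec, pieces)
    rng = np.random.default_rng(spec.seed)

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    refseq = {
        chrom: bases[rng.integers(0, 4, size=length)].tobytes().decode()
        for chrom, length in contigs.items()
    }
    hap = "".join(
        refseq[p.chrom][p.start:p.end] if p.orientation == FORWARD
        else revcomp(refseq[p.chrom][p.start:p.end])
        for p in pieces
    )
    offsets = np.concatenate([[0], np.cumsum([p.length for p in pieces])])[:-1]
    boundary_junction = {int(off): j for j, off in enumerate(offsets[1:])}

    phase_set = spec.phase_set if spec.phase_set is not None else spec.window_start
    total_len = len(hap)
    n_reads = int(round(spec.coverage * total_len / spec.read_length))
    reads = []
    support = {}
    for i in range(n_reads):
        start = int(rng.integers(-spec.read_length + 200, total_len - 200))
        length = max(800, int(rng.normal(spec.read_length, spec.read_length_sd)))
        r0, r1 = max(0, start), min(total_len, start + length)
        unphased = rng.random() < spec.unphased_fraction
        mapq0 = rng.random() < spec.mapq0_fraction
        if r1 - r0 < 500:
            continue
        ideal = _read_to_segments(pieces, offsets, r0, r1)
        crossed = [boundary_junction[int(off)] for off in offsets[1:]
                   if r0 < int(off) < r1]
        if any(j in spec.suppress_junctions for j in crossed):
            continue
        segs = _apply_jitter(ideal, rng, spec.jitter, r1 - r0)
        if mapq0:
            segs = [Segment(s.chrom, s.ref_start, s.ref_end, s.strand,
                            s.clip_left, s.clip_right, 0) for s in segs]
        for s1, s2, j in zip(segs, segs[1:], crossed):
            exit_brk, entry_brk = junctions[j]
            if _exit_entry_ok(s1, s2, exit_brk, entry_brk,
                              DEFAULT_TOL, DEFAULT_MIN_CLIP):
                key = (min(exit_brk, entry_brk), max(exit_brk, entry_brk))
                support.setdefault(key, set()).add(f"{spec.name}_read{i:05d}")
        reads.append(ReadTruth(
            name=f"{spec.name}_read{i:05d}", hap_start=r0, hap_end=r1,
            segments=segs, ideal_segments=ideal,
            haplotype=None if unphased else spec.haplotype,
            phase_set=None if unphased else phase_set,
        ))

    os.makedirs(str(out_dir), exist_ok=True)
    bam_path = os.path.join(str(out_dir), f"{spec.name}.bam")
    vcf_path = os.path.join(str(out_dir), f"{spec.name}.vcf")
    _write_bam(spec, bam_path, contigs, refseq, hap, reads, pieces, rng, phase_set)
    _write_vcf(spec, vcf_path, contigs, refseq, junctions)

    kept = [j for i, j in enumerate(junctions) if i not in spec.suppress_junctions]
    truth = _truth_network(spec, pieces, junctions, kept)
    return SimResult(
        spec=spec, bam_path=bam_path, vcf_path=vcf_path, truth=truth,
        junctions=junctions,
        junction_support={k: len(v) for k, v in support.items()},
        reads=reads, pieces=pieces, contigs=contigs, refseq=refseq,
    )


def _plain_reads(rng, chrom, lo, hi, contig_len, coverage, read_length, sd,
                 prefix, haplotype, phase_set, unphased_fraction,
                 mapq0_fraction=0.0):
    """Unclipped reference-consistent reads tiling [lo, hi)."""
    out = []
    span = hi - lo
    n = int(round(coverage * span / read_length))
    for i in range(n):
        start = int(rng.integers(lo - read_length + 200, hi - 200))
        length = max(800, int(rng.normal(read_length, sd)))
        unphased = rng.random() < unphased_fraction
        mapq = 0 if rng.random() < mapq0_fraction else 60
        r0 = max(0, start)
        r1 = min(contig_len, start + length)
        if r1 - r0 < 500:
            continue
        out.append((f"{prefix}{i:05d}", chrom, r0, r1,
                    None if unphased else haplotype,
                    None if unphased else phase_set, mapq))
    return out


def _write_bam(spec, bam_path, contigs, refseq, hap, reads, pieces, rng, phase_set):
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in contigs.items()],
    }
    tid = {name: i for i, name in enumerate(contigs)}
    records = []

    def sam_fields(seg: Segment, rlen: int):
        # clips are stored in reference orientation, matching SAM records
        left, right = seg.clip_left, seg.clip_right
        return (f"{left}S" if left else "") + f"{seg.length}M" + (
            f"{right}S" if right else "")

    for rt in reads:
        rlen = rt.hap_end - rt.hap_start
        seq = hap[rt.hap_start:rt.hap_end]
        primary_idx = max(range(len(rt.segments)), key=lambda k: rt.segments[k].length)
        sa_items = [
            f"{s.chrom},{s.ref_start + 1},{s.strand},{sam_fields(s, rlen)},{s.mapq},0"
            for s in rt.segments
        ]
        for k, seg in enumerate(rt.segments):
            rec = pysam.AlignedSegment()
            rec.query_name = rt.name
            rec.reference_id = tid[seg.chrom]
            rec.reference_start = seg.ref_start
            rec.mapping_quality = seg.mapq
            rec.cigarstring = sam_fields(seg, rlen)
            rec.query_sequence = seq if seg.strand == "+" else revcomp(seq)
            flag = 0
            if seg.strand == "-":
                flag |= 16
            if k != primary_idx:
                flag |= 2048
            rec.flag = flag
            tags = []
            if len(rt.segments) > 1:
                others = [sa_items[j] for j in range(len(rt.segments)) if j != k]
                tags.append(("SA", ";".join(others) + ";"))
            if rt.haplotype is not None:
                tags.append(("HP", rt.haplotype))
                tags.append(("PS", rt.phase_set))
            rec.set_tags(tags)
            records.append(rec)

    ref_regions = {}
    anchor_lo = spec.window_start - spec.flank
    anchor_hi = spec.window_end + spec.flank
    ref_regions[spec.anchor_chrom] = (anchor_lo, anchor_hi)
    for p in pieces:
        lo, hi = ref_regions.get(p.chrom, (p.start, p.end))
        ref_regions[p.chrom] = (min(lo, p.start - spec.flank // 2),
                                max(hi, p.end + spec.flank // 2))
    plain = []
    if spec.ref_coverage > 0:
        for chrom in sorted(ref_regions, key=natural_contig_key):
            lo, hi = ref_regions[chrom]
            lo = max(0, lo)
            plain.extend(_plain_reads(
                rng, chrom, lo, hi, contigs[chrom], spec.ref_coverage,
                spec.read_length, spec.read_length_sd,
                f"{spec.name}_ref_{chrom}_", 2, phase_set, spec.unphased_fraction,
                spec.mapq0_fraction,
            ))
    if spec.spike_region and spec.spike_coverage > 0:
        chrom, lo, hi = spec.spike_region
        plain.extend(_plain_reads(
            rng, chrom, lo, hi, contigs[chrom], spec.spike_coverage,
            min(spec.read_length, max(1000, hi - lo)), spec.read_length_sd // 2,
            f"{spec.name}_spike_", None, None, 1.0,
        ))
    for name, chrom, r0, r1, hp, ps, mapq in plain:
        rec = pysam.AlignedSegment()
        rec.query_name = name
        rec.reference_id = tid[chrom]
        rec.reference_start = r0
        rec.mapping_quality = mapq
        rec.cigarstring = f"{r1 - r0}M"
        rec.query_sequence = refseq[chrom][r0:r1]
        rec.flag = 0
        if hp is not None:
            rec.set_tags([("HP", hp), ("PS", ps)])
        records.append(rec)

    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name,
                                r.flag))
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(bam_path)


def _bnd_alt(ref_base: str, partner: Break) -> str:
    if partner.side == SIDE_RIGHT:
        bracket = f"[{partner.chrom}:{partner.pos + 1}["
    else:
        bracket = f"]{partner.chrom}:{partner.pos}]"
    return bracket


def _write_vcf(spec, vcf_path, contigs, refseq, junctions):
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Breakend mate">',
        '##ALT=<ID=BND,Description="Breakend">',
    ]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    recs = []
    for j, (exit_brk, entry_brk) in enumerate(junctions):
        ids = (f"{spec.name}_j{j}_a", f"{spec.name}_j{j}_b")
        for rid, mate_id, brk, partner in (
            (ids[0], ids[1], exit_brk, entry_brk),
            (ids[1], ids[0], entry_brk, exit_brk),
        ):
            if brk.side == SIDE_LEFT:
                pos1 = brk.pos
                base = refseq[brk.chrom][brk.pos - 1]
                alt = base + _bnd_alt(base, partner)
            else:
                pos1 = brk.pos + 1
                base = refseq[brk.chrom][brk.pos]
                alt = _bnd_alt(base, partner) + base
            info = f"SVTYPE=BND;MATEID={mate_id}"
            recs.append((brk.chrom, pos1, rid, base, alt, info))
    recs.sort(key=lambda r: (natural_contig_key(r[0]), r[1], r[2]))
    for chrom, pos1, rid, base, alt, info in recs:
        lines.append(f"{chrom}\t{pos1}\t{rid}\t{base}\t{alt}\t.\tPASS\t{info}")
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# scripted scenario suite


def category_suite(base_seed: int = 1) -> list:
    """One spec per scripted rearrangement category.

    Covers balanced inversion, unbalanced inversions (one and two flanking
    deletions, the latter with the 716/284/38 bp size triple), non-tandem
    duplication + deletion (plain and inverted), balanced translocation with
    flanking duplication, tandem duplication, pure deletion, a phased
    deletion pair, a five-row multi-block deletion+inversion event, an
    evidence-poor unresolved inversion, and an over-the-block-cap chain.
    """
    chrom = "chr1"
    specs = []

    def add(name, seed_offset, **kw):
        specs.append((name, RearrangementSpec(
            name=name, seed=base_seed + seed_offset, **kw)))

    add("inv", 0, anchor_chrom=chrom, window_start=30_000, window_end=35_000,
        blocks=(SegmentSpec(chrom, 30_000, 35_000, INVERTED),))
    add("inv-del", 1, anchor_chrom=chrom, window_start=30_000, window_end=36_000,
        blocks=(SegmentSpec(chrom, 31_000, 36_000, INVERTED),))
    add("del-inv-del", 2, anchor_chrom=chrom,
        window_start=30_000, window_end=31_038,
        blocks=(SegmentSpec(chrom, 30_716, 31_000, INVERTED),))
    add("dup-del", 3, anchor_chrom=chrom, window_start=30_000, window_end=33_000,
        blocks=(SegmentSpec(chrom, 25_000, 26_500, FORWARD),))
    add("nontandem-inv-del", 4, anchor_chrom=chrom,
        window_start=30_000, window_end=33_000,
        blocks=(SegmentSpec(chrom, 25_000, 26_500, INVERTED),))
    add("balanced-trans-dup", 5, anchor_chrom="chr2",
        window_start=40_000, window_end=40_000,
        blocks=(SegmentSpec("chr12", 50_000, 56_000, FORWARD),
                SegmentSpec("chr12", 58_000, 63_000, FORWARD),
                SegmentSpec("chr2", 39_600, 40_000, FORWARD)))
    add("tandem-dup", 6, anchor_chrom=chrom,
        window_start=30_000, window_end=33_000,
        blocks=(SegmentSpec(chrom, 30_000, 33_000, FORWARD),
                SegmentSpec(chrom, 30_000, 33_000, FORWARD)))
    add("del", 7, anchor_chrom=chrom, window_start=30_000, window_end=35_000)
    add("phased-del-pair", 8, anchor_chrom=chrom,
        window_start=30_000, window_end=62_000,
        blocks=(SegmentSpec(chrom, 33_000, 59_000, FORWARD),))
    add("multi-block-del-inv", 9, anchor_chrom=chrom,
        window_start=30_000, window_end=58_000,
        blocks=(SegmentSpec(chrom, 42_000, 46_000, FORWARD),
                SegmentSpec(chrom, 34_000, 38_000, INVERTED),
                SegmentSpec(chrom, 50_000, 54_000, INVERTED)))
    add("unresolved", 10, anchor_chrom=chrom,
        window_start=30_000, window_end=55_000,
        blocks=(SegmentSpec(chrom, 30_000, 55_000, INVERTED),),
        suppress_junctions=(1,))
    # 25 small deletions chained by spanning reads: 25 junctions, 51 blocks
    keep = tuple(
        SegmentSpec(chrom, 30_000 + 2_000 + 4_000 * i,
                    30_000 + 4_000 + 4_000 * i, FORWARD)
        for i in range(24)
    )
    add("many-block", 11, anchor_chrom=chrom,
        window_start=30_000, window_end=128_000, blocks=keep)
    return specs
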