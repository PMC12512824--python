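"""Reading SV VCFs, alignment evidence and BED files; JSON/BED output.

VCF positions are kept 1-based inside :class:`SVCall` exactly as printed in
the file; :func:`call_breaks` is the single place where they are converted to
the package's 0-based inter-base break coordinates:

* breakend (BND) records: a left-anchored breakend at POS ``p`` breaks after
  the 1-based base ``p`` (0-based coordinate ``p``); a right-anchored one
  breaks before it (coordinate ``p - 1``);
* symbolic alleles: POS is the base before the event and END its last base,
  so POS and END are already the 0-based flanking break coordinates.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import pysam

from . import __version__
from .model import (
    INVERTED,
    SIDE_LEFT,
    SIDE_RIGHT,
    AlignmentEvidence,
    Break,
    Connection,
    GenomicBlock,
    SVCall,
    SVNetwork,
    Segment,
    natural_contig_key,
)

log = logging.getLogger(__name__)

_BND_RE = re.compile(
    r"^(?P<lead>[A-Za-z.]*)"
    r"(?P<open>[\[\]])(?P<chrom>[^\[\]:]+):(?P<pos>\d+)(?P<close>[\[\]])"
    r"(?P<trail>[A-Za-z.]*)$"
)

SYMBOLIC_TYPES = ("DEL", "DUP", "INV", "INS")


class VcfParseError(ValueError):
    pass


def _parse_bnd_alt(alt: str):
    """Decode breakend bracket notation.

    Returns (this_side, mate_chrom, mate_pos_1based, mate_side) or ``None``
    for a single breakend (``N.`` / ``.N``) with no partner coordinates.
    """
    if re.fullmatch(r"[A-Za-z]+\.|\.[A-Za-z]+", alt):
        return None
    m = _BND_RE.match(alt)
    if m is None or m.group("open") != m.group("close"):
        raise VcfParseError(f"malformed breakend ALT {alt!r}")
    # Leading bases => the reference is anchored to the left of this breakend.
    this_side = SIDE_LEFT if m.group("lead") else SIDE_RIGHT
    # '[' => the partner piece extends rightward of the mate position,
    # i.e. the mate is right-anchored; ']' => left-anchored.
    mate_side = SIDE_RIGHT if m.group("open") == "[" else SIDE_LEFT
    return this_side, m.group("chrom"), int(m.group("pos")), mate_side


def _record_svtype(rec) -> str:
    svtype = rec.info.get("SVTYPE")
    if svtype:
        return str(svtype)
    alt = rec.alts[0] if rec.alts else ""
    if alt.startswith("<") and alt.endswith(">"):
        return alt.strip("<>").split(":")[0]
    if "[" in alt or "]" in alt:
        return "BND"
    raise VcfParseError(f"record {rec.id} at {rec.chrom}:{rec.pos} has no SV type")


def _carries_alt(rec, sample_id: str) -> bool:
    """True unless the named sample is present and genotyped hom-ref/missing."""
    if sample_id not in (rec.samples.keys() if rec.samples else ()):
        return True
    gt = rec.samples[sample_id].get("GT")
    if gt is None:
        return True
    return any(a not in (None, 0) for a in gt)


def parse_sv_vcf(vcf_path, sample_id: str = "") -> list:
    """Parse an SV VCF into :class:`SVCall` endpoint pairs.

    BND records are paired via MATEID (each pair emitted once); a BND whose
    mate is absent is retained with ``single_ended=True``.  Symbolic DEL/DUP/
    INS records become one call; INV becomes two calls, one per inverted
    junction.
    """
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot read VCF {vcf_path}: {exc}") from exc

    bnds = {}
    calls = []
    with vf:
        for rec in vf:
            if rec.alts is None:
                continue
            svtype = _record_svtype(rec)
            if svtype == "BND":
                bnds[rec.id] = rec_info = {
                    "id": rec.id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,  # pysam .pos is 1-based
                    "alt": rec.alts[0],
                    "mate_id": rec.info.get("MATEID"),
                    "keep": _carries_alt(rec, sample_id),
                }
                if isinstance(rec_info["mate_id"], tuple):
                    rec_info["mate_id"] = rec_info["mate_id"][0]
            elif svtype in SYMBOLIC_TYPES:
                if not _carries_alt(rec, sample_id):
                    continue
                pos = rec.pos  # 1-based POS, base before the event
                end = rec.stop  # 1-based END (== 0-based exclusive)
                if svtype == "INS":
                    end = pos
                if end < pos:
                    raise VcfParseError(
                        f"record {rec.id}: END {end} before POS {pos}"
                    )
                if svtype == "INV":
                    for suffix, sides in ((".1", (SIDE_LEFT, SIDE_LEFT)),
                                          (".2", (SIDE_RIGHT, SIDE_RIGHT))):
                        calls.append(SVCall(
                            id=f"{rec.id}{suffix}", svtype="INV",
                            chrom_a=rec.chrom, pos_a=pos,
                            chrom_b=rec.chrom, pos_b=end,
                            orient_a=sides[0], orient_b=sides[1],
                            sample_id=sample_id,
                        ))
                else:
                    orients = {
                        "DEL": (SIDE_LEFT, SIDE_RIGHT),
                        "DUP": (SIDE_RIGHT, SIDE_LEFT),
                        "INS": (SIDE_LEFT, SIDE_RIGHT),
                    }[svtype]
                    calls.append(SVCall(
                        id=rec.id, svtype=svtype,
                        chrom_a=rec.chrom, pos_a=pos,
                        chrom_b=rec.chrom, pos_b=end,
                        orient_a=orients[0], orient_b=orients[1],
                        sample_id=sample_id,
                    ))
            else:
                log.debug("skipping non-SV record %s (%s)", rec.id, svtype)

    calls.extend(_pair_bnds(bnds, sample_id))
    calls.sort(key=lambda c: (natural_contig_key(c.chrom_a), c.pos_a, c.id))
    return calls


def _pair_bnds(bnds: dict, sample_id: str):
    done = set()
    for rid in sorted(bnds):
        if rid in done:
            continue
        rec = bnds[rid]
        if not rec["keep"]:
            continue
        parsed = _parse_bnd_alt(rec["alt"])
        mate_id = rec["mate_id"]
        mate = bnds.get(mate_id) if mate_id else None
        if parsed is None:
            yield SVCall(
                id=rid, svtype="BND",
                chrom_a=rec["chrom"], pos_a=rec["pos"],
                chrom_b=rec["chrom"], pos_b=rec["pos"],
                orient_a=SIDE_LEFT, orient_b=SIDE_LEFT,
                mate_id=mate_id, sample_id=sample_id, single_ended=True,
            )
            done.add(rid)
            continue
        this_side, mchrom, mpos, mate_side = parsed
        single = mate is None
        if mate_id and mate is None:
            log.warning("BND %s references absent mate %s; kept single-ended",
                        rid, mate_id)
        if mate is not None:
            done.add(mate_id)
        done.add(rid)
        yield SVCall(
            id=rid, svtype="BND",
            chrom_a=rec["chrom"], pos_a=rec["pos"],
            chrom_b=mchrom, pos_b=mpos,
            orient_a=this_side, orient_b=mate_side,
            mate_id=mate_id, sample_id=sample_id, single_ended=single,
        )


def call_breaks(call: SVCall) -> list:
    """Convert one call's 1-based VCF endpoints to 0-based :class:`Break`s."""

    def convert(pos: int, side: str) -> int:
        if call.svtype == "BND":
            return pos if side == SIDE_LEFT else pos - 1
        return pos  # symbolic: POS/END are already flanking 0-based coords

    breaks = [Break(call.chrom_a, convert(call.pos_a, call.orient_a), call.orient_a)]
    if not call.single_ended:
        breaks.append(
            Break(call.chrom_b, convert(call.pos_b, call.orient_b), call.orient_b)
        )
    return breaks


def extract_breaks(calls, merge_window: int = 10) -> list:
    """Collapse call endpoints into unique breaks.

    Endpoints on the same chromosome and side within ``merge_window`` bp of
    each other (transitively) collapse to one break at the cluster minimum.
    """
    by_group = {}
    for call in calls:
        for brk in call_breaks(call):
            by_group.setdefault((brk.chrom, brk.side), set()).add(brk.pos)
    out = []
    for (chrom, side), positions in by_group.items():
        cluster_start = None
        prev = None
        for pos in sorted(positions):
            if cluster_start is None or pos - prev > merge_window:
                cluster_start = pos
            prev = pos
            out.append(Break(chrom, cluster_start, side))
    uniq = sorted(set(out), key=lambda b: (natural_contig_key(b.chrom), b.pos, b.side))
    return uniq


def assign_call_breaks(calls, breaks, merge_window: int = 10) -> dict:
    """Map each call id to the merged breaks its endpoints collapsed into."""
    by_group = {}
    for brk in breaks:
        by_group.setdefault((brk.chrom, brk.side), []).append(brk)
    mapping = {}
    for call in calls:
        assigned = []
        for brk in call_breaks(call):
            candidates = by_group.get((brk.chrom, brk.side), [])
            near = [b for b in candidates if abs(b.pos - brk.pos) <= merge_window]
            if near:
                assigned.append(min(near, key=lambda b: abs(b.pos - brk.pos)))
        mapping[call.id] = assigned
    return mapping


# ---------------------------------------------------------------------------
# alignment evidence


def _cigar_stats(cigar: str):
    """(clip_left, clip_right, ref_len) from a CIGAR string."""
    ops = re.findall(r"(\d+)([MIDNSHP=X])", cigar)
    if not ops:
        raise ValueError(f"bad CIGAR {cigar!r}")
    clip_left = int(ops[0][0]) if ops[0][1] in "SH" else 0
    clip_right = int(ops[-1][0]) if len(ops) > 1 and ops[-1][1] in "SH" else 0
    ref_len = sum(int(n) for n, op in ops if op in "MDN=X")
    return clip_left, clip_right, ref_len


def _segment_from_record(rec) -> Segment:
    clip_left = clip_right = 0
    ct = rec.cigartuples or []
    if ct and ct[0][0] in (4, 5):
        clip_left = ct[0][1]
    if len(ct) > 1 and ct[-1][0] in (4, 5):
        clip_right = ct[-1][1]
    return Segment(
        chrom=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        strand="-" if rec.is_reverse else "+",
        clip_left=clip_left,
        clip_right=clip_right,
        mapq=rec.mapping_quality,
    )


def _segments_from_sa(sa_tag: str):
    for entry in sa_tag.rstrip(";").split(";"):
        if not entry:
            continue
        chrom, pos, strand, cigar, mapq, _nm = entry.split(",")
        clip_left, clip_right, ref_len = _cigar_stats(cigar)
        start = int(pos) - 1
        yield Segment(
            chrom=chrom, ref_start=start, ref_end=start + ref_len,
            strand=strand, clip_left=clip_left, clip_right=clip_right,
            mapq=int(mapq),
        )


def _read_order_key(seg: Segment) -> int:
    # Offset of the segment's first base in the original read.
    return seg.clip_left if seg.strand == "+" else seg.clip_right


def collect_alignment_evidence(bam_path, breaks, window: int = 1000,
                               reference=None) -> list:
    """Gather split-read evidence around break neighbourhoods.

    Fetches reads overlapping ``[pos - window, pos + window]`` for every
    break, reconstructs each read's full segment chain from its SA tag and
    records HP/PS phasing tags.  Each read name is returned exactly once.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    af = pysam.AlignmentFile(str(bam_path), reference_filename=reference)
    regions = {}
    for brk in breaks:
        regions.setdefault(brk.chrom, []).append(
            (max(0, brk.pos - window), brk.pos + window)
        )
    chosen = {}
    with af:
        valid = set(af.references)
        for chrom, ivs in sorted(regions.items()):
            if chrom not in valid:
                log.warning("contig %s absent from BAM header; breaks skipped", chrom)
                continue
            merged = []
            for start, end in sorted(ivs):
                if merged and start <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            for start, end in merged:
                for rec in af.fetch(chrom, start, end):
                    if rec.is_unmapped or rec.is_secondary:
                        continue
                    prev = chosen.get(rec.query_name)
                    if prev is None or (prev.is_supplementary and not rec.is_supplementary):
                        chosen[rec.query_name] = rec

    evidence = []
    for name in sorted(chosen):
        rec = chosen[name]
        segments = [_segment_from_record(rec)]
        if rec.has_tag("SA"):
            segments.extend(_segments_from_sa(rec.get_tag("SA")))
        segments.sort(key=_read_order_key)
        evidence.append(AlignmentEvidence(
            read_name=name,
            segments=segments,
            haplotype=rec.get_tag("HP") if rec.has_tag("HP") else None,
            phase_set=rec.get_tag("PS") if rec.has_tag("PS") else None,
        ))
    return evidence


# ---------------------------------------------------------------------------
# JSON / BED output


@dataclass
class JsonDocument:
    sample_id: str
    events: list = field(default_factory=list)  # list[SVNetwork]
    version: str = __version__


def _break_dict(brk: Break) -> dict:
    return {"chrom": brk.chrom, "pos": brk.pos, "side": brk.side}


def _break_from(d) -> Break:
    return Break(d["chrom"], d["pos"], d["side"])


def network_to_dict(net: SVNetwork) -> dict:
    return {
        "sample_id": net.sample_id,
        "variant_ids": sorted(net.variant_ids),
        "resolved": net.resolved,
        "filters": sorted(net.filters),
        "region": {c: [int(s), int(e)] for c, (s, e) in sorted(net.region.items())},
        "start_break": _break_dict(net.start_break) if net.start_break else None,
        "breaks": [_break_dict(b) for b in sorted(net.breaks)],
        "connections": [
            {
                "break_1": _break_dict(c.break_1),
                "break_2": _break_dict(c.break_2),
                "kind": c.kind,
                "inverted": c.inverted,
                "support": c.support,
                "phase_set": c.phase_set,
                "is_junction": c.is_junction,
            }
            for c in sorted(net.connections, key=lambda c: (c.break_1, c.break_2, c.kind))
        ],
        "blocks": [
            {
                "chrom": b.chrom,
                "start": b.start,
                "end": b.end,
                "label": b.label,
                "orientation": b.orientation,
                "sample_order_index": b.sample_order_index,
                "support": b.support,
            }
            for b in sorted(
                net.blocks,
                key=lambda b: (
                    b.sample_order_index is None,
                    b.sample_order_index or 0,
                    natural_contig_key(b.chrom),
                    b.start,
                ),
            )
        ],
    }


def network_from_dict(d: dict) -> SVNetwork:
    return SVNetwork(
        breaks=[_break_from(b) for b in d["breaks"]],
        connections=[
            Connection(
                break_1=_break_from(c["break_1"]),
                break_2=_break_from(c["break_2"]),
                kind=c["kind"],
                inverted=c["inverted"],
                support=c["support"],
                phase_set=c["phase_set"],
                is_junction=c["is_junction"],
            )
            for c in d["connections"]
        ],
        blocks=[
            GenomicBlock(
                chrom=b["chrom"], start=b["start"], end=b["end"],
                orientation=b["orientation"],
                sample_order_index=b["sample_order_index"],
                label=b["label"], support=b["support"],
            )
            for b in d["blocks"]
        ],
        start_break=_break_from(d["start_break"]) if d["start_break"] else None,
        resolved=d["resolved"],
        variant_ids=list(d["variant_ids"]),
        sample_id=d["sample_id"],
        region={c: (s, e) for c, (s, e) in d["region"].items()},
        filters=list(d["filters"]),
    )


def write_json(doc: JsonDocument, path) -> None:
    payload = {
        "sample_id": doc.sample_id,
        "svblocks_version": doc.version,
        "events": [network_to_dict(net) for net in doc.events],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> JsonDocument:
    with open(path) as fh:
        payload = json.load(fh)
    return JsonDocument(
        sample_id=payload["sample_id"],
        version=payload["svblocks_version"],
        events=[network_from_dict(d) for d in payload["events"]],
    )


def write_event_bed(doc: JsonDocument, path) -> None:
    """Per-event block annotations as BED6 (name = event:label:orientation:index)."""
    lines = []
    for i, net in enumerate(doc.events):
        for blk in net.blocks:
            idx = blk.sample_order_index if blk.sample_order_index is not None else "."
            name = f"event{i}:{blk.label}:{blk.orientation}:{idx}"
            strand = "-" if blk.orientation == INVERTED else "+"
            lines.append((blk.chrom, blk.start, blk.end, name, blk.support, strand))
    lines.sort(key=lambda t: (natural_contig_key(t[0]), t[1], t[3]))
    with open(path, "w") as fh:
        for line in lines:
            fh.write("\t".join(str(x) for x in line) + "\n")


def read_bed(path) -> list:
    """Read BED3+ intervals as (chrom, start, end, name); bad lines skipped."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError):
                log.warning("%s line %d: malformed BED line skipped", path, ln)
                continue
            name = fields[3] if len(fields) > 3 else ""
            out.append((chrom, start, end, name))
    return out
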