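"""Core domain types for complex structural variant reconstruction.

Coordinates are 0-based half-open everywhere inside the package; conversion
to and from 1-based VCF coordinates happens only at the VCF boundary.

A ``Break`` is an inter-base genomic coordinate where the sample haplotype
departs from the reference.  Its ``side`` records which flank of the break is
reference-consistent:

* ``"left"``  -- aligned sequence runs up to ``pos`` and is clipped there
  (reads exit the reference moving rightward);
* ``"right"`` -- aligned sequence begins at ``pos`` (reads enter the
  reference moving rightward).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

SIDE_LEFT = "left"
SIDE_RIGHT = "right"

FORWARD = "forward"
INVERTED = "inverted"


def natural_contig_key(name: str):
    """Sort key ordering contigs the way humans read them (chr2 < chr12)."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def contig_sort_key(chrom: str, contig_order: Optional[dict] = None):
    if contig_order is not None and chrom in contig_order:
        return (0, contig_order[chrom], "")
    return (1, 0, natural_contig_key(chrom))


@dataclass(frozen=True, order=True)
class Break:
    """A breakpoint: (chrom, pos, side) is the identity key."""

    chrom: str
    pos: int
    side: str

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"break position must be >= 0, got {self.pos}")
        if self.side not in (SIDE_LEFT, SIDE_RIGHT):
            raise ValueError(f"invalid break side {self.side!r}")


@dataclass
class SVCall:
    """One SV record reduced to an endpoint pair with orientations."""

    id: str
    svtype: str  # BND, DEL, DUP, INV, INS
    chrom_a: str
    pos_a: int  # 0-based break coordinate (already converted from VCF)
    chrom_b: str
    pos_b: int
    orient_a: str  # side of break A ("left"/"right")
    orient_b: str
    mate_id: Optional[str] = None
    sample_id: str = ""
    single_ended: bool = False


@dataclass(frozen=True)
class Segment:
    """One aligned segment of a (possibly split) read, reference orientation.

    ``clip_left``/``clip_right`` are the clip lengths before ``ref_start`` and
    after ``ref_end`` respectively, independent of strand.
    """

    chrom: str
    ref_start: int
    ref_end: int
    strand: str  # '+' or '-'
    clip_left: int
    clip_right: int
    mapq: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class AlignmentEvidence:
    """One read's full segment chain, ordered by position in the read."""

    read_name: str
    segments: list  # list[Segment], read order
    haplotype: Optional[int] = None
    phase_set: Optional[int] = None


@dataclass
class Connection:
    """An evidence-backed link between two breaks.

    ``kind`` is ``"spanned"`` (read evidence) or ``"phased"`` (haplotype /
    phase-block linkage).  ``is_junction`` distinguishes novel adjacencies
    (the sample jumps between the two break sides) from reference-consistent
    links spanned by reads or inferred from phasing.
    """

    break_1: Break
    break_2: Break
    kind: str  # "spanned" | "phased"
    inverted: bool
    support: int
    phase_set: Optional[int] = None
    is_junction: bool = True
    read_names: frozenset = frozenset()

    def __post_init__(self):
        if (self.break_2.chrom, self.break_2.pos, self.break_2.side) < (
            self.break_1.chrom,
            self.break_1.pos,
            self.break_1.side,
        ):
            self.break_1, self.break_2 = self.break_2, self.break_1
        if self.support < 1:
            raise ValueError("connections require support >= 1")

    def other(self, brk: Break) -> Break:
        return self.break_2 if brk == self.break_1 else self.break_1


@dataclass
class GenomicBlock:
    """A reference interval between adjacent breaks.

    ``sample_order_index`` is the block's position in the reconstructed
    sample haplotype, or ``None`` when the block is absent from it (deleted,
    or an unvisited donor flank).  A block traversed k times appears as k
    entries sharing label and coordinates.
    """

    chrom: str
    start: int
    end: int
    orientation: str = FORWARD
    sample_order_index: Optional[int] = None
    label: str = ""
    support: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty block {self.chrom}:{self.start}-{self.end}")


@dataclass
class SVNetwork:
    """One connected rearrangement event."""

    breaks: list = field(default_factory=list)
    connections: list = field(default_factory=list)
    blocks: list = field(default_factory=list)
    start_break: Optional[Break] = None
    resolved: bool = False
    variant_ids: list = field(default_factory=list)
    sample_id: str = ""
    region: dict = field(default_factory=dict)  # chrom -> (start, end)
    filters: list = field(default_factory=list)

    def chroms(self, contig_order=None):
        return sorted(self.region, key=lambda c: contig_sort_key(c, contig_order))

    def span(self) -> int:
        """Total breakpoint span (sum over chromosomes, margins excluded)."""
        total = 0
        for chrom in self.region:
            pos = [b.pos for b in self.breaks if b.chrom == chrom]
            if len(pos) >= 2:
                total += max(pos) - min(pos)
        return total

    def sample_blocks(self):
        """Blocks present in the sample haplotype, in sample order."""
        present = [b for b in self.blocks if b.sample_order_index is not None]
        return sorted(present, key=lambda b: b.sample_order_index)


def block_labels(n: int):
    """A, B, ... Z, AA, AB, ... labels for n reference-ordered blocks."""
    out = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = chr(ord("A") + j % 26) + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def structure_summary(net: SVNetwork) -> dict:
    """Orientation/order summary used to compare reconstructions to truth.

    Captures everything that defines the rearrangement structure: the
    reference block partition, the sample-order sequence of (label,
    orientation) pairs, the set of deleted (sample-absent) blocks, and the
    resolved flag.  Support counts and provenance are deliberately excluded.
    """
    ref_axis = sorted(
        {(b.chrom, b.start, b.end, b.label) for b in net.blocks},
        key=lambda t: (natural_contig_key(t[0]), t[1]),
    )
    sample_seq = [(b.label, b.orientation) for b in net.sample_blocks()]
    labelled = {t[3] for t in ref_axis}
    present = {b.label for b in net.blocks if b.sample_order_index is not None}
    return {
        "reference_blocks": ref_axis,
        "sample_sequence": sample_seq,
        "deleted_blocks": sorted(labelled - present),
        "resolved": net.resolved,
    }


@dataclass
class FilterConfig:
    coverage_fold_limit: float = 5.0
    low_mapq_fraction_limit: float = 0.2
    mapq_floor: int = 5
    keep_simple: bool = False
    block_cap: int = 20

    def __post_init__(self):
        if self.coverage_fold_limit <= 0 or self.mapq_floor < 0:
            raise ValueError("filter limits must be positive")
        if not 0 <= self.low_mapq_fraction_limit <= 1:
            raise ValueError("low_mapq_fraction_limit must be in [0, 1]")
        if self.block_cap < 2:
            raise ValueError("block_cap must be >= 2")


@dataclass
class PlotSpec:
    image_format: str = "svg"  # svg | png | pdf
    show_labels: bool = True
    annotation_tracks: list = field(default_factory=list)  # [(name, bed_path)]
    thickness_saturation: int = 30  # support count at which rows reach max height
    dpi: int = 150

    def __post_init__(self):
        if self.image_format not in ("svg", "png", "pdf"):
            raise ValueError(f"unsupported image format {self.image_format!r}")

    def thickness(self, support: int) -> float:
        """Piecewise-linear, saturating map from support to row thickness."""
        frac = min(max(support, 0), self.thickness_saturation) / self.thickness_saturation
        return 0.25 + 0.55 * frac


__all__ = [
    "Break",
    "SVCall",
    "Segment",
    "AlignmentEvidence",
    "Connection",
    "GenomicBlock",
    "SVNetwork",
    "FilterConfig",
    "PlotSpec",
    "SIDE_LEFT",
    "SIDE_RIGHT",
    "FORWARD",
    "INVERTED",
    "block_labels",
    "structure_summary",
    "natural_contig_key",
    "contig_sort_key",
    "replace",
]
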