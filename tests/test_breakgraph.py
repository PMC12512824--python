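"""Break matching, connection building, networks, and block ordering."""

import random

import pytest

from svblocks import formats_io
from svblocks.breakgraph import (
    build_networks,
    connect_breaks,
    count_support,
    find_start_break,
    match_alignment_to_break,
)
from svblocks.model import (
    FORWARD,
    INVERTED,
    SIDE_LEFT,
    SIDE_RIGHT,
    AlignmentEvidence,
    Break,
    Connection,
    Segment,
    structure_summary,
)
from conftest import single_event, summaries


def clipped_read(name, chrom, ref_start, ref_end, clip_left=0, clip_right=0,
                 strand="+", hp=None, ps=None):
    seg = Segment(chrom, ref_start, ref_end, strand, clip_left, clip_right, 60)
    return AlignmentEvidence(read_name=name, segments=[seg], haplotype=hp,
                             phase_set=ps)


@pytest.mark.parametrize("offset", range(0, 16))
def test_clip_matching_tolerance_sweep(offset):
    """Clips within 10 bp of the break match; beyond that they do not."""
    brk = Break("chr1", 1000, SIDE_LEFT)
    ev = clipped_read("r", "chr1", 500, 1000 + offset, clip_right=2000)
    assert match_alignment_to_break(ev, brk, tol=10, min_clip=50) == (offset <= 10)


def test_insignificant_clips_and_wrong_side_do_not_match():
    brk = Break("chr1", 1000, SIDE_LEFT)
    short_clip = clipped_read("r1", "chr1", 500, 1000, clip_right=30)
    assert not match_alignment_to_break(short_clip, brk, min_clip=50)
    wrong_side = clipped_read("r2", "chr1", 1000, 1500, clip_left=2000)
    assert not match_alignment_to_break(wrong_side, brk)
    assert match_alignment_to_break(wrong_side, Break("chr1", 1000, SIDE_RIGHT))


def test_deletion_connection_support_equals_simulated_spanning_reads(suite):
    scenario = suite["del"]
    net = single_event(scenario)
    junctions = [c for c in net.connections if c.is_junction]
    assert len(junctions) == 1
    conn = junctions[0]
    assert not conn.inverted
    key = (min(conn.break_1, conn.break_2), max(conn.break_1, conn.break_2))
    assert conn.support == scenario.sim.junction_support[key]
    assert conn.support > 0


def test_inversion_connections_are_inverted(suite):
    net = single_event(suite["inv"])
    junctions = [c for c in net.connections if c.is_junction]
    assert len(junctions) == 2
    assert all(c.inverted for c in junctions)


def test_phased_pair_linked_only_through_phasing(suite):
    """Two distant deletions share a network via HP/PS; unphased they split."""
    scenario = suite["phased-del-pair"]
    net = single_event(scenario)
    kinds = {c.kind for c in net.connections}
    assert "phased" in kinds
    phased = [c for c in net.connections if c.kind == "phased"]
    assert all(not c.is_junction and c.support >= 1 for c in phased)

    calls = formats_io.parse_sv_vcf(scenario.sim.vcf_path)
    breaks = formats_io.extract_breaks(calls)
    evidence = formats_io.collect_alignment_evidence(scenario.sim.bam_path, breaks)
    stripped = [AlignmentEvidence(ev.read_name, ev.segments, None, None)
                for ev in evidence]
    nets = build_networks(connect_breaks(breaks, stripped))
    assert len(nets) == 2, "without phasing tags the deletions stay separate"


def test_connected_components_match_bruteforce_oracle():
    """Network grouping equals transitive closure on random small graphs."""

    def oracle(edges):
        comps = []
        for a, b in edges:
            touching = [c for c in comps if a in c or b in c]
            merged = {a, b}.union(*touching) if touching else {a, b}
            comps = [c for c in comps if c not in touching] + [merged]
        return {frozenset(c) for c in comps}

    rng = random.Random(7)
    for _ in range(1000):
        n = rng.randint(2, 10)
        nodes = [Break(rng.choice(["chr1", "chr2"]), rng.randrange(100, 10_000) * 10
                       + i, rng.choice([SIDE_LEFT, SIDE_RIGHT]))
                 for i in range(n)]
        edges = []
        for _ in range(rng.randint(1, 12)):
            a, b = rng.sample(nodes, 2)
            edges.append((a, b))
        conns = [Connection(a, b, kind="spanned", inverted=False, support=1)
                 for a, b in edges]
        got = {frozenset(net.breaks) for net in build_networks(conns)}
        assert got == oracle(edges)


@pytest.mark.parametrize("name,expected_sample", [
    ("del", [("A", FORWARD), ("C", FORWARD)]),
    ("inv", [("A", FORWARD), ("B", INVERTED), ("C", FORWARD)]),
    ("tandem-dup", [("A", FORWARD), ("B", FORWARD), ("B", FORWARD), ("C", FORWARD)]),
    ("del-inv-del", [("A", FORWARD), ("C", INVERTED), ("E", FORWARD)]),
    ("multi-block-del-inv", [("A", FORWARD), ("E", FORWARD), ("C", INVERTED),
                             ("G", INVERTED), ("I", FORWARD)]),
])
def test_block_order_reconstruction(suite, name, expected_sample):
    recon, truth = summaries(suite[name])
    assert recon == truth
    assert recon["sample_sequence"] == expected_sample


def test_sample_indices_are_contiguous(suite):
    for scenario in suite.values():
        for net in scenario.doc.events:
            idx = sorted(b.sample_order_index for b in net.blocks
                         if b.sample_order_index is not None)
            assert idx == list(range(len(idx)))


def test_reference_labels_increase_with_coordinate(suite):
    from svblocks.model import natural_contig_key

    for scenario in suite.values():
        for net in scenario.doc.events:
            axis = sorted({(b.chrom, b.start, b.label) for b in net.blocks},
                          key=lambda t: (natural_contig_key(t[0]), t[1]))
            labels = [t[2] for t in axis]
            assert labels == sorted(labels, key=lambda s: (len(s), s))


def test_start_break_is_reference_consistent_entry(suite):
    net = single_event(suite["dup-del"])
    # the entry from the left flank, not the (lower-coordinate) donor exit
    assert net.start_break == Break("chr1", 30_000, SIDE_LEFT)
    # standalone query agrees with the ordering pass
    assert find_start_break(net) == net.start_break


def test_translocation_spans_two_chromosomes(suite):
    net = single_event(suite["balanced-trans-dup"])
    recon, truth = summaries(suite["balanced-trans-dup"])
    assert recon == truth
    assert set(net.region) == {"chr2", "chr12"}
    assert net.start_break.chrom == "chr2"
    dup_labels = [b.label for b in net.sample_blocks()]
    assert dup_labels.count("B") == 2, "short chr2 region duplicated"


def test_skip_rule_drops_unmatched_breaks_without_crashing(suite):
    """Breaks with no clipped alignments nearby vanish from the graph."""
    scenario = suite["del"]
    calls = formats_io.parse_sv_vcf(scenario.sim.vcf_path)
    breaks = formats_io.extract_breaks(calls)
    evidence = formats_io.collect_alignment_evidence(scenario.sim.bam_path, breaks)
    left = Break("chr1", 30_000, SIDE_LEFT)
    kept = [ev for ev in evidence
            if not match_alignment_to_break(ev, left, tol=10, min_clip=50)]
    conns = connect_breaks(breaks, kept)
    assert conns == []
    assert build_networks(conns) == []


def test_unresolved_when_one_junction_lacks_evidence(suite):
    scenario = suite["unresolved"]
    net = single_event(scenario)
    assert not net.resolved
    assert net.start_break is None
    assert all(b.sample_order_index is None for b in net.blocks)
    recon, truth = summaries(scenario)
    assert recon == truth


def test_block_cap_marks_unresolved_but_keeps_partition(suite):
    scenario = suite["many-block"]
    net = single_event(scenario)
    assert not net.resolved
    assert len(net.blocks) > 20
    assert structure_summary(net) == structure_summary(scenario.sim.truth)


def test_support_monotone_under_added_reads(suite):
    """Extra reads supporting existing junctions change counts, not topology."""
    scenario = suite["inv"]
    calls = formats_io.parse_sv_vcf(scenario.sim.vcf_path)
    breaks = formats_io.extract_breaks(calls)
    evidence = formats_io.collect_alignment_evidence(scenario.sim.bam_path, breaks)
    doubled = evidence + [
        AlignmentEvidence("copy_" + ev.read_name, ev.segments, ev.haplotype,
                          ev.phase_set)
        for ev in evidence
    ]
    base = connect_breaks(breaks, evidence)
    more = connect_breaks(breaks, doubled)
    key = lambda c: (c.break_1, c.break_2, c.kind, c.inverted, c.is_junction)
    assert {key(c) for c in base} == {key(c) for c in more}
    for c_base in base:
        c_more = next(c for c in more if key(c) == key(c_base))
        assert c_more.support == 2 * c_base.support


def test_block_support_is_max_of_bounding_connections(suite):
    net = single_event(suite["inv"])
    count_support(net)
    boundary = {}
    for conn in net.connections:
        for brk in (conn.break_1, conn.break_2):
            boundary[brk.pos] = max(boundary.get(brk.pos, 0), conn.support)
    for blk in net.blocks:
        expected = max(boundary.get(blk.start, 0), boundary.get(blk.end, 0))
        assert blk.support == expected


def test_same_read_primary_plus_supplementary_counted_once(suite):
    """Support never exceeds the number of distinct simulated read names."""
    scenario = suite["tandem-dup"]
    net = single_event(scenario)
    n_reads = len({rt.name for rt in scenario.sim.reads})
    for conn in net.connections:
        assert conn.support <= n_reads
        assert conn.support == len(conn.read_names or range(conn.support))
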