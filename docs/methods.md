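# Methods

## Model

A germline rearrangement on one haplotype is modelled as an alternation of
**reference walks** and **novel-adjacency jumps**. The inputs provide two
complementary views of the jumps:

* the SV VCF names candidate break coordinates and their orientations
  (breakend bracket semantics; symbolic alleles expanded to breakends);
* split long reads realize them: when a read crosses a junction its
  alignment splits into segments, and the clipped reference coordinates of
  adjacent segments mark the two break sides the haplotype joins.

Internally all coordinates are 0-based half-open; a break is the inter-base
coordinate *(chrom, pos)* plus a *side* ∈ {left, right} saying which flank is
reference-consistent. This resolves the four breakend bracket forms and lets
one genomic position carry two distinct break sides (as at both ends of an
inversion). Conversion to/from 1-based VCF happens in exactly one module
(`formats_io`).

### Matching rule

An alignment supports a break if some segment boundary has clip length
≥ `min_clip` and the clipped reference coordinate lies within `tol` of the
break. `tol` defaults to 10 bp, the same tolerance used to merge nearby VCF
endpoints. `min_clip` defaults to 50 bp: well above clip noise from
high-accuracy long reads, well below SV-scale clips. Breaks with no matching
alignment are skipped instead of aborting the event, since callers can emit
coordinates the local alignments do not reproduce.

### Connections and networks

Adjacent segment pairs of one read that match two break sides yield a
*spanned junction* connection (`inverted` if the strands differ). A read
crossing two junctions additionally links the two inner breaks with a
reference-adjacency connection (kind `spanned`, `is_junction = False`); the
extra boolean keeps the spec's two-value `kind` while letting the traversal
distinguish novel adjacencies from reference-consistent links. Variant pairs
with no read spanning both are joined by a *phased* connection when their
supporting reads share an `HP`/`PS` assignment, they are reference-adjacent
among matched breaks, lie on one chromosome, and are within a configurable
gap (default 500 kb — phase blocks are finite and longer-range linkage in a
germline sample is rarely informative). Phased connections are restricted to
adjacent breaks of *different* read-spanned components to avoid emitting a
clique across every co-phased variant. Support of a spanned connection is
the number of distinct read names (a primary plus its supplementaries count
once); for a phased connection it is the smaller of the two breaks'
phased-read counts, a deliberately conservative summary since no single read
witnesses the pair. Networks are connected components of the
break/connection graph (small union-find; an independent brute-force
component oracle backs it in the tests).

### Block ordering (traversal)

Within a network, break positions partition each chromosome's window
(breakpoint span plus a flanking margin of 10 % of the span, at least
100 bp) into labelled reference blocks A, B, C, … The sample structure is
recovered by a backtracking search over traversals that

1. start at a junction exit reached from reference-consistent flanking
   sequence — *flank-entered*: some read's **first** segment, with an
   essentially unclipped read start, is clipped at that coordinate;
2. alternate strictly positive-length reference walks with junction jumps,
   consuming **every junction exactly once** (direction flips when a jump
   lands on a left-side break);
3. end moving forward into the right flank.

Positive-length walks matter: zero-length walks would let two junctions
compose into an adjacency the reads never witnessed, creating spurious
alternative orders. The flank-entry requirement disambiguates structures
that share a junction set but differ in the orientation of interior material
(e.g. an inverted non-tandem duplication read in the wrong direction). The
lowest (contig order from the BAM header, then coordinate) valid start wins;
a network with no valid start, more than one complete traversal from the
chosen start, a search exceeding a fixed expansion budget, or more than
`block_cap` = 20 blocks is reported **unresolved** — kept in the output with
its reference partition, never silently dropped and never guessed. How the
original tool breaks such ties is not derivable from the available
description; unresolved-rather-than-guessed is this package's own policy.

Walks map onto partition blocks: each visit emits a block entry with a
sample-order index and orientation, so deleted blocks have no index and a
block traversed k times appears k times. Block support is the maximum over
the connections bounding it.

## Filters

* **Coverage / mapping quality** (before output): drop when any block's mean
  depth deviates more than `coverage_fold_limit` (default 5×) from the
  background in either direction, or when the fraction of overlapping reads
  with MAPQ < 5 exceeds 0.2. Background depth is the median over 200 seeded
  random 500 bp windows, excluding zero-coverage windows — a covered-genome
  median that behaves sensibly on sparse or targeted alignments. The
  thresholds are conventional round numbers chosen to pass uniform data and
  fail gross artifacts; all are configurable.
* **Simple networks** (at plot time, optional, on by default): suppress
  networks whose breaks are on one chromosome, number at most two distinct
  positions, and contain no inverted block; single-ended breakends are also
  suppressed. Both filters are order-independent and every drop records a
  machine-readable reason in the JSON.

## Synthetic data

`svblocks.simulate` scripts a rearrangement as a reference window replaced by
an ordered list of oriented reference segments inside reference-consistent
flanks. From one seed it synthesizes a random reference (chr-style names to
exercise contig ordering), samples variant-haplotype reads uniformly along
the rearranged haplotype, decomposes each read into reference segments with
exact soft-clips, `SA` chains and strand flips, adds `HP`/`PS` tags, and
writes a coordinate-sorted indexed BAM plus a truth VCF of mated breakends
and the expected reconstruction. Defaults emulate one haplotype of a ~20×
phased HiFi sample: 6 kb ± 0.8 kb reads, 2 bp clip jitter at junctions
(exercising, not defeating, the 10 bp tolerance), 10 % unphased reads.
Reference-haplotype (`HP=2`) reads are emitted at equal coverage so
heterozygous depth signatures (deleted ≈ 0.5×, duplicated ≈ 1.5×) are
realistic for the coverage filter. Optional degradations (a coverage spike,
a MAPQ-0 fraction, suppression of one junction's reads) exist to exercise
the filters and the skip rule.

The scripted suite covers balanced inversion; inversion with one and with
two flanking deletions (the latter using a 716 bp deletion, 284 bp
inversion, 38 bp deletion); plain and inverted non-tandem duplication each
followed by a deletion; a balanced translocation of two donor blocks with a
short flanking duplication at the acceptor; tandem duplication; pure
deletion; a phased deletion pair separated beyond read length; a five-row
multi-block deletion+inversion event; an evidence-poor unresolved inversion;
and a 25-junction deletion chain that exceeds the block cap.

**What the simulator does not model:** sequencing errors and quality
realism, mappability (every read is placed where it was generated, MAPQ is a
scripted constant), indels inside segments, somatic mixtures, and breakpoint
microhomology beyond the scripted jitter. Passing the suite therefore shows
the reconstruction logic is correct for clean split-read evidence with
realistic coverage, phasing and clip noise; it does not certify behaviour on
alignment artifacts, which is precisely what the coverage/MAPQ filters and
the unresolved flag are for on real data.

## Numerical and design notes

* Determinism everywhere: seeded sampling for the background-depth estimate,
  sorted iteration orders, JSON with sorted keys, SVG written with a fixed
  hash salt and no timestamp — two runs on identical inputs are
  byte-identical (JSON, BED, SVG, HTML, and simulator outputs).
* Row thickness is a piecewise-linear function of support saturating at 30
  reads, so one deep junction cannot dominate a figure.
* Multi-chromosome events render one x-panel per chromosome, widths
  proportional to spanned length with a minimum fraction per panel.
* The viewer's filter semantics live in one Python function
  (`viewer.filter_rows`) and the page's JavaScript is generated to mirror
  it; range bounds are inclusive and a chromosome filter keeps any row
  touching a selected contig so translocations stay visible. The JavaScript
  route is mirrored by construction, not executed in the test suite (no
  browser engine is exercised).
* Degenerate inputs: an empty VCF yields an empty document; a zero-block
  network refuses to render; a BND whose mate is missing is retained,
  flagged single-ended, and suppressed by the simple filter; contigs absent
  from the BAM header produce a warning and are skipped.
* One sample is processed per extraction (selected by VCF sample name when
  genotypes are present — records genotyped hom-ref/missing for that sample
  are ignored); the viewer merges any number of extracted samples.
* Problem sizes in the tests and acceptance script (tens-of-kilobase events,
  ~20× per haplotype, 12 scenarios) are chosen so the whole suite re-derives
  every scenario from scratch in a few minutes on one core — large enough
  for every junction to collect double-digit read support, small enough to
  iterate on.

## Known limitations

* Copy number beyond what junction multiplicity implies is not used: a
  triplication whose junction set equals a duplication's reconstructs as the
  duplication.
* Phased connections link only reference-adjacent co-phased variants; a
  chain of three co-phased deletions merges pairwise, but no attempt is made
  to phase *across* phase-set boundaries.
* Breakpoints closer than the 10 bp merge window collapse; sub-10 bp blocks
  are not representable.
* CRAM is supported by passing a reference path through; no reference cache
  management is attempted.
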