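# svblocks

Reconstruction and visualization of **complex germline structural variants
(SVs)** from phased long-read alignments.

Long-read SV callers report individual breakends and symbolic alleles, but a
single rearranged haplotype — an inversion flanked by deletions, a non-tandem
duplication, a balanced translocation with a small flanking duplication —
scatters across several VCF records that are hard to assemble mentally or in
a read-level browser. `svblocks` takes an SV VCF plus the phased, aligned
reads (BAM/CRAM with `SA`, `HP`, `PS` tags), reconstructs the order and
orientation of the rearranged genomic blocks on the sample haplotype, and
renders each event as a block diagram with a filterable HTML table viewer.
It is aimed at genomicists reviewing germline complex SVs in long-read
(e.g. HiFi) data, one sample at a time, with multi-sample viewing.

## Method

1. **Breaks.** Every VCF endpoint becomes a break *(chrom, pos, side)*,
   where *side* says which flank continues in reference orientation
   (breakend bracket semantics; symbolic DEL/DUP/INV/INS are expanded to the
   equivalent breakends). Endpoints within 10 bp merge.
2. **Evidence.** Reads around each break are collected and each read's full
   split-alignment chain is rebuilt from its `SA` tag. An alignment supports
   a break if it carries significant soft-clipping (≥ 50 bp by default)
   whose reference coordinate is within 10 bp of the break; a break with no
   such alignment is skipped.
3. **Connections.** Adjacent segments of one read that match two breaks form
   a *spanned* junction (a novel adjacency; `inverted` when the strands
   differ); variants with no spanning read but haplotype-consistent support
   (shared `HP`/`PS`) are joined by *phased* connections. Support is the
   number of distinct read names.
4. **Networks.** Connected components of the break/connection graph are
   rearrangement networks. Within each network, a traversal that starts
   where reads enter from reference-consistent flanking sequence and uses
   every junction exactly once recovers the sample order and orientation of
   the reference blocks between breaks (up to 20 blocks; larger or ambiguous
   networks are reported as unresolved rather than guessed).
5. **Filters & output.** Networks in regions of abnormal depth or pervasive
   low mapping quality are flagged; results go to per-sample JSON and BED.
   At plot time an optional filter suppresses *simple* networks (one or two
   same-chromosome forward breaks with no inverted block), so review focuses
   on complex events. Each retained event becomes an SVG/PNG/PDF diagram —
   reference axis on top, sample rows beneath, thickness ∝ support, plus a
   chain track — indexed by a self-contained HTML table with click-to-filter
   on variant ID, variant count, sample, region size and chromosome.

A first-class simulator (`svblocks.simulate`) scripts arbitrary
rearrangements and emits the matching reference, phased split reads with
correct soft-clips/`SA` chains/strands, a truth VCF of mated breakends, and
the expected reconstruction — so the whole pipeline is testable offline.

## Worked example

Simulate a 284 bp inversion flanked by 716 bp and 38 bp deletions at ~20×,
then reconstruct it:

```bash
python - <<'PY'
from svblocks.simulate import category_suite, simulate
simulate(dict(category_suite(1))["del-inv-del"], "sim")
PY
svblocks extract --bam sim/del-inv-del.bam --vcf sim/del-inv-del.vcf \
    --sample HG001 --out-dir out
svblocks plot out/HG001_events.json --bam sim/del-inv-del.bam --out-dir out
svblocks viewer out/HG001_events.json --out-dir out
```

Inspecting the JSON:

```text
resolved: True
reference order: A B C D E
sample order:    A C' E
connection chr1:30000/l -- chr1:31000/l  kind=spanned inverted=True  support=18
connection chr1:30716/r -- chr1:31038/r  kind=spanned inverted=True  support=18
```

Reading this: the reference window splits into five blocks A–E at the four
break coordinates. The sample haplotype runs A, then C in inverted
orientation (`C'`), then E — so B (716 bp) and D (38 bp) are deleted and C
(284 bp) is inverted, each junction supported by 18 distinct spanning reads.
The image `out/images/HG001_chr1-29896-31142.svg` shows the same structure
graphically and `out/images/index.html` is the table viewer.

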