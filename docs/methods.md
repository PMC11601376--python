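# Methods

This note documents the model behind each pipeline stage, the parameters
that matter, the synthetic data the package is validated on, and the known
limits of both.

## Input model and bad-read recruitment

The caller consumes a reference FASTA and a position-sorted, indexed BAM
whose reads carry fragment barcodes in the `BX` tag (linked-read / SLR
data: 5–100 kbp fragments sheared from one haplotype, barcoded, then
short-read sequenced, so reads sharing a barcode share a fragment of
origin).

A read pair is classified *badly aligned* when

* (a) every base of both mates has Phred quality strictly above
  `qual_min` (default 20) — a poorly placed read must not simply be a
  poorly sequenced read — **and**
* (b) at least one mate is unmapped, aligned to a contig outside the
  primary-contig allowlist, or has strictly more than `clip_frac_max`
  (default 0.20) of its bases clipped, **or**
* (c) at least one mate carries an `AM` tag equal to 0 (an aligner-specific
  signal that the read could not be clustered with same-barcode reads).

Interpretation choices (the rules admit several readings): "higher than
20" and "more than 20 %" are read strictly; per-base minimum quality, not
mean; hard clips count toward the clipped fraction with the pre-clipping
read length as denominator; an absent `AM` tag never triggers (c), since
only one aligner family emits it. The allowlist defaults to the human
primary chromosomes and falls back to all contigs of the supplied
reference for non-human genomes; it is configurable.

Badly aligned pairs go into a barcode-indexed map so that, later, the
pairs belonging to any barcode list are retrieved in output-size time.
These are precisely the reads whose sequence content (inserted sequence,
breakpoint junctions) the reference-based alignment could not place.

## Segmentation and barcode selection

The reference is tiled into `segment_length` = 50 kbp windows overlapping
by `segment_overlap` = 10 kbp. The overlap is a lower bound on the largest
deletion detectable (an event spanning a whole overlap zone never lies
inside one segment); events shorter than the overlap always have a segment
that contains them fully. A trailing window shorter than the overlap is
merged into its predecessor rather than emitted.

For each segment, a barcode is selected when ≥ `min_pairs` = 3 read pairs
align inside the segment with an alignment-start span > `min_span` =
5 kbp. A genuine fragment overlapping the segment scatters reads across
tens of kbp; a spurious barcode (one mismapped pair) fails the span test.
Span is measured between alignment start positions — the difference
against fragment-inferred ends is below one read length.

The segment read set is then: aligned reads of selected barcodes (pairs
completed by mate lookup when one mate falls outside), plus the badly
aligned pairs of those barcodes, deduplicated by read name. In hybrid
mode, long reads overlapping the segment are attached, capped at
`long_read_cap` = 100 by descending segment overlap (ties by name).

## Local assembly

Per segment, a directed de Bruijn graph is built from the k-mers of the
short reads (k = 55 by default, auto-lowered to read length − 10 and
forced odd; k-mers with multiplicity < `solid_threshold` = 2 are dropped).
Reads are used in the orientation stored in the BAM — aligners emit SEQ
reference-forward, and the simulator does the same for placed-unmapped
mates — so no reverse-complement twin bookkeeping is needed; the cost is
that raw, orientation-random FASTQ input is not supported directly.

Simplification is deliberately *relaxed* compared to an isolate assembler,
because the sample is diploid and heterozygous variation must survive:

* tips (dead ends) are clipped only when shorter than `tip_len_max` = 2k
  **and** below `tip_cov_max` = 0.5 × the length-weighted median unitig
  coverage of the segment graph;
* a bulge side is removed only when it is short (< `bulge_len_max` = 2k),
  dominated by its sibling (< `bulge_cov_ratio_max` = 0.2 ×) **and** weak
  in absolute terms (< `het_keep_ratio` = 0.25 × median). A balanced bulge
  — the signature of a heterozygous variant — is always preserved.

Simplification iterates to a fixpoint and is idempotent.

Path extension is greedy from the longest unvisited unitig, and its
junction policy encodes the diploid/repeat trade-offs:

* **Bulge forking.** At a two-way junction whose branches reconverge on
  ordinary backbone, both traversals are emitted (bounded by `fork_cap`),
  so both alleles of a het variant appear as full-length contigs. There is
  no path deduplication; redundant calls collapse later at the VCF level.
  Reconvergence on a unitig at more than `fork_meet_cov_max` = 1.75 × the
  median coverage is rejected: such a meeting point is a collapsed repeat
  shared by several loci, not an allele junction.
* **Tandem-loop unrolling.** A candidate branch that closes a short cycle
  (period ≤ `tandem_period_max` = 1 kbp) back to the current unitig is a
  collapsed tandem tract; it is traversed round(loop coverage / median)
  times (capped at `loop_unroll_max`) before taking the exit. The estimate
  uses the graph median rather than local path context so that paths
  traversing the tract from either direction spell the same sequence and
  deduplicate. Copy number is approximate — for heterozygous tracts it is
  roughly halved — but the breakpoint position, which evaluation keys on,
  is exact.
* **Chained-repeat traversal.** A *long*-period cycle means the current
  unitig is a repeat occurring at several loci with the loop body being
  the sequence between them (e.g. the same mobile-element donor inserted
  twice in one segment). The body is traversed exactly once — never
  re-using body unitigs — which visits the loci in genome order; exiting
  early would splice distant loci and fake a deletion, and looping again
  would spell a duplication chimera.
* **Stub skipping.** Junction branches that are dead-ended, shorter than
  `long_tip_min` and below `stub_cov_max` = 0.5 × median coverage are
  artifact stubs (typically junction fragments of a repeat's *other* loci
  recruited through the bad-read map) and never block extension when
  exactly one continuing branch remains. A short dead branch at normal
  coverage — e.g. backbone truncated at the segment boundary — is treated
  as a real continuation.
* **Join guarding (the tip-vicinity rule).** Crossing a *join* (entering a
  unitig with other predecessors, or symmetrically when extending
  backwards) is refused when a long dead end (≥ `long_tip_min` = 10k bp)
  has its dead endpoint within `tip_vicinity` = 5 kbp of the junction —
  the footprint of a coverage dropout, which in a repeat would otherwise
  be spelled as a deletion-like false join. Distances are
  endpoint-resolved (each unitig contributes a head and a tail node), so
  a long backbone unitig whose far end lies outside the radius does not
  veto the crossing. A path that is itself shorter than `long_tip_min`
  also never crosses a join: artifact stubs must not be spliced through
  repeats. The rule can be disabled (`tip_vicinity_rule: false` /
  `--no-tip-vicinity`) to demonstrate the false join it prevents.

These thresholds are package choices, selected to reproduce the intended
qualitative behaviours (het preservation, dropout safety, tandem
spanning) on the synthetic benchmark; all are exposed in the `assembly:`
config section.

**Hybrid mode.** Long reads never contribute k-mers to the graph — at
0.1–1 % error they would seed spurious parallel paths and distort the
coverage statistics that simplification relies on. Instead they close
gaps at the contig level: a long read supports joining contig A to contig
B when an exact `anchor_len` = 21-mer from A's tail window and one from
B's head window occur in the read in order; the read's intervening
sequence (≤ `max_gap_fill`) fills the gap. The best-supported join per
contig end wins; ties whose gap-adjacent sequence is identical are fork
variants of one junction and are all performed; genuine ties abstain.
Joins chain over a few recursive rounds. Spliced-in long-read sequence
carries its errors (≤ 1 %), which surface as scattered 1–2 bp mismatches
around a rescued event — harmless under positional matching.

## Calling

Contigs are re-aligned to the whole reference. The default backend is an
anchor-chaining aligner: unique 31-mers of the reference are indexed, the
contig's matching k-mers are chained by longest increasing subsequence,
collinear blocks become exact-match runs, and the regions between blocks
are aligned with bit-parallel edit distance (edlib) — a pure insertion or
deletion between exact anchors therefore surfaces as one contiguous I/D
operation, and a contig with no credible chain (< 40 anchors) is reported
unaligned rather than force-fitted. Plain whole-contig edit distance is
not SV-aware: under unit costs, absorbing a large deletion as a noisy
alignment of the downstream flank (≈ 0.5 edits/bp) is cheaper than one
long gap (1 edit/bp), which silently destroys deletion calls. A
`minimap2` backend (subprocess, asm5 preset) is available and serves as
an independent cross-check in the test suite.

Each I/D operation becomes a candidate call; positions follow the VCF
anchor-base convention and calls are left-normalized (shifted to their
leftmost equivalent placement). Calls are kept only within their segment
± `call_margin` = 500 bp: the overlap zone is interior to the
neighbouring segment, so nothing is lost, while read-map-only "ghost"
assemblies of loci tens of kbp away (fragments extend far past the
segment) cannot emit partial-evidence near-duplicates. The global call
set is size-filtered to [`min_sv`, `max_sv`] = [50, 10,000] bp inclusive,
deduplicated on exact (type, contig, position, length) — an optional
`dedup_slack` collapses same-length calls within N bp, off by default —
sorted, and written as VCF 4.2 with anchor-base REF/ALT spelling,
`SVTYPE`/`SVLEN`/`END` annotations and the full parameter set in the
header. Genotypes are not inferred (GT is `.`).

## The simulator

The generator emulates the study conditions end to end; its defaults *are*
the benchmark scenario:

* **Genome.** One 300 kbp random contig (GC 0.5). Optional identical
  repeat copies (`repeat_copies`/`repeat_positions`) create
  assembly-hard regions for the negative controls.
* **Variants.** 30 events — 10 deletions, 10 random-sequence insertions,
  5 mobile-element-like insertions (one fixed 300 bp synthetic donor
  reused across events, so copies are repetitive genome-wide, as a real
  mobile-element family is; a 6 kbp donor can be enabled for longer
  events) and 5 tandem-like insertions (a novel 60 bp motif expanded 3–8
  fold) — half heterozygous, lengths 50–5,000 bp, ≥ 1 kbp apart, ≥ 6 kbp
  from contig ends. Truth is written as a phased VCF on original
  reference coordinates.
* **Linked reads.** Fragment lengths uniform in [5, 100] kbp; fragment
  start positions range over [−(ℓ−1), L−1] and fragments are clipped to
  the contig (dropping clipped fragments below the 5 kbp shearing floor),
  which keeps coverage uniform to the contig ends — with naive interior
  placement a toy-scale contig loses most of its coverage within one
  fragment length (≈ 52 kbp!) of each end, an artifact no
  chromosome-scale library exhibits. One barcode per fragment (an
  optional collision rate re-uses barcodes, emulating real multiplexing);
  read pairs Poisson-sampled at 0.2× within-fragment coverage, 2×150 bp,
  insert 350 ± 35 bp, error-free by default (`slr_error_rate` available);
  total coverage 40×.
* **Projection alignment.** Each read's true origin is projected through
  the haplotype→reference block map: fully collinear reads align
  perfectly; reads crossing an SV breakpoint are soft-clipped to their
  largest collinear piece; reads entirely inside inserted sequence become
  placed-unmapped records at the insertion anchor. This mimics exactly
  the signatures the bad-read rules detect, without requiring an external
  aligner. Dropout intervals suppress every pair whose reference
  footprint (both sides of a deletion junction) touches them.
* **Long reads.** Lengths uniform in [9,000, 12,000] bp, per-read error
  uniform in [0.001, 0.01], errors i.i.d. per base (60 % substitutions,
  20 % insertions, 20 % deletions), truthful CIGARs maintained through
  error application; coverage configurable (5× in the hybrid scenario).

Identical config + seed gives byte-identical FASTA/BAM/VCF outputs.

What the simulator does **not** model: empirical quality profiles, PCR
duplicates and chimeras, GC-coverage bias (beyond explicit dropouts),
barcode sequencing errors, real mobile-element or STR sequences, and
reference gaps. Passing the synthetic benchmark therefore demonstrates the
algorithmic behaviour of the pipeline — barcode recruitment, diploid
preservation, dropout safety, hybrid rescue — not calibrated performance
on any real platform.

## Evaluation protocol

Calls and truth are size-filtered with the same inclusive window, split by
type, and matched greedily one-to-one by increasing breakpoint distance
with a 100 bp cutoff; positions and types only — no length or sequence
similarity terms. On the simulator's event spacing (≥ 1 kbp ≫ 2×100 bp)
greedy matching is provably optimal, and the suite checks it against an
exhaustive assignment. Precision, recall and F1 are reported per type and
combined; undefined ratios print as NA. Type-split call lists can be
exported for external benchmarking tools.

## Problem sizes used in validation

The automated suite runs the full benchmark (300 kbp, 30 SVs, 40×,
~39 k read pairs) in SLR mode, the same genome with three engineered
500 bp dropouts plus 5× long reads in hybrid mode, and several 50–100 kbp
single-segment scenarios (het preservation, repeat/dropout control,
overlap dedup). These sizes exercise every code path — multi-segment
tiling, overlap dedup, barcode rescue, forking, unrolling, gap closing —
while one end-to-end run stays in the ten-second range.

## Known limitations

* Several copies of the *same* insertion donor within one segment (or
  within fragment reach of it) make the donor a multi-entry/multi-exit
  repeat node. Two chained loci are resolved by the loop-traversal rule;
  three or more, or pairs farther apart than `cycle_search_len`, are left
  uncalled (never misjoined). Resolving them would require read-pair
  threading through the graph, which is out of scope — and repeat-family
  insertions are the weakest class of every assembly-based caller.
* Tandem copy numbers are coverage estimates; the reported insertion
  length for a tandem tract can be off by integer motif multiples even
  though the position is exact.
* Deletions longer than the segment overlap (10 kbp by default) cannot be
  detected, by construction of the tiling.
* No genotyping, phasing, inversion/translocation/duplication
  classification, or breakend records.
* The assembler assumes orientation-normalized input (BAM SEQ
  convention); it does not build a bidirected graph.
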