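# Methods

`gallsift` implements a subtractive ("host-discriminant") shotgun analysis
for detecting foreign-DNA insertion sites in a plant host genome from paired
healthy/gall tissue sequencing, together with the synthetic-data generator
used to validate it and an in-silico PCR module for the gall marker assay.
This note records the model, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## The detection model

A DNA insertion in gall-cell genomes leaves two signatures in shotgun data:

1. reads spanning a host/foreign junction fail to map to the host reference
   and are absent from the healthy sample;
2. assembling those gall-exclusive reads produces *hybrid/fusion contigs*
   whose 5′, 3′ or both ends align to the host while their core does not.

The pipeline realizes this in six stages: (i) semiperfect mapping of each
sample's reads to the host; (ii) k-mer subtraction of the gall unmapped reads
against the healthy unmapped reads; (iii) de Bruijn assembly of the
gall-exclusive remainder; (iv) length filtering and identity dereplication
of contigs; (v) seed–chain–extend re-alignment of contigs to the host with
CIGAR output, confidence filtering, and end-anchor classification; (vi)
read-back support counting. Internally all coordinates are 0-based
half-open; reports are 1-based.

### Semiperfect mapping

A placement is *semiperfect* when every on-reference base of the oriented
read equals the reference base (N on either side counts as a match), bases
may overhang chromosome ends, and at least `ceil(L/2)` of the read lies on
the reference. Candidates come from a canonical 31-mer index; probing the
read at stride `ceil(L/2) − k + 1` guarantees that any valid placement
leaves one probed window inside its on-reference span, so for N-free
sequence the anchored search equals an exhaustive all-position scan (tested
property). Reads containing N fall back to probing every window; a
placement whose entire on-reference span lacks an N-free window is not
anchorable — such reads simply stay "unmapped", which is conservative for
this pipeline. One substitution error anywhere voids a placement: with
0.1 % per-base error, ~14 % of 150-bp host reads are expected unmapped,
which is precisely why stage (ii) exists.

### Shared-read subtraction

A gall unmapped read is *shared* when ≥ 50 % of its 31-mer windows (by
canonical form) occur anywhere in the healthy unmapped read set, otherwise
*exclusive*. The containment threshold (0.5) and k (31) are decisions, not
published values: exact read identity would let every erroneous host read
through, while containment at half the windows removes host-error reads
(whose clean k-mers are well covered by the healthy unmapped fraction) yet
keeps junction reads with ≥ half foreign content. Both are configurable.

### Assembly

Single-k (31) de Bruijn graph over canonical k-mers, abundance pruning at
`min_kmer_count = 2` (removes singleton error k-mers at 16× depth), unitig
extraction, one round of tip clipping (< 2k with a dead end) with
recompaction, no bubble popping. Fragmentation from uncorrected errors only
reduces recall, which the recovery tests measure. Contigs < 200 bp are then
dropped and redundancy removed greedily by descending length at ≥ 95 %
identity — the published thresholds. Identity is operationalized as
`(len − edit_distance)/len` with the contig aligned as an infix of the
longer contig (edlib, both orientations), plus the same test on the contig's
central 90 % window to realize the containment fraction. The published
description names the alignment tool but not its subject database;
self-dereplication is our interpretation, and externally assembled contigs
can replace this stage entirely via FASTA import.

### Contig re-alignment and confidence

Exact 19-mer seeds on both strands are clustered by diagonal (band 32,
colinear gap ≤ 500) and each cluster is extended by local alignment
restricted to the cluster's window (match +1, mismatch −4, gap of length L
costs 6 + L; alignments scoring < 30 dropped). The DP kernel is
Bio.Align.PairwiseAligner; the seeding, windowing, CIGAR/soft-clip
construction and everything downstream are this package's code, and the
test suite checks that the seeded score equals full-reference dynamic
programming on alignable contigs. Because clusters split at diagonal shifts
beyond the band, an internal insertion yields two soft-clipped alignments;
the classifier also accepts the equivalent single-alignment encoding with an
insertion op and treats the two identically (tested).

Mapping confidence is a documented surrogate for aligner-specific mapping
quality: for competing placements (contig intervals overlapping by > 50 % of
the shorter), the best gets `round(60·(s1 − s2)/s1)`, ties and secondary
placements get 0, and the published threshold (≥ 20) is applied to it.
Defining competition by contig-interval overlap is essential: the two host
anchors of one hybrid contig occupy disjoint contig intervals and must not
annihilate each other's confidence.

### Classification and site estimation

Anchors are host-aligned contig intervals ≥ 30 bp at ≥ 95 % identity from
confidence-passing alignments (insertion ops ≥ 30 bp split an alignment into
separate anchors). A contig is FULL_MATCH when anchors cover all but
2×10 bp of it (or the residual core is < 30 bp); FIVE_PRIME / THREE_PRIME /
BOTH when qualifying anchors sit at the respective ends around a ≥ 30 bp
unanchored core; NONE otherwise, with a warning when overlapping anchors
disagree on chromosome. BOTH additionally requires one chromosome,
consistent strand, and a reference gap in [−30, 200]: the lower bound admits
junction microhomology (reported as a negative gap, e.g. −6 for a 6-bp
duplication), the upper bound small host deletions at the junction; both
bounds are our defaults, exposed in config. The insertion point is the
reference coordinate at the core-facing edge of each anchor; the canonical
single-point summary for BOTH calls is the right edge of the ref-leftmost
anchor, which equals the planted position in the simulator's splice
convention regardless of contig orientation.

Support is the number of exclusive reads placing on the contig with ≤ 2
mismatches (half-read overhang allowed); calls with support < 3 are
discarded — the published rule — unless allowlisted, in which case they are
retained and flagged (the published analysis kept three such contigs on
annotation evidence; which ones is not identifiable, so the allowlist is a
user input). `junction_support` (placements spanning a junction by ≥ 10 bp
on each side) is reported as a stricter diagnostic but not filtered on.

The endophyte "synteny" check is a containment summary: exclusive contigs
≥ 200 bp aligning into an isolate genome at ≥ 95 % edit-distance identity
support the isolate's endophytic status.

## The synthetic-data generator

The generator emulates the study's sequencing design: a multi-chromosome
host (default 2 × 1 Mb i.i.d. bases at GC 0.5), a gall genome derived from
it by splicing `n_insertions = 10` foreign segments of 500–2,000 bp at
positions ≥ 300 bp from chromosome ends and ≥ 2 read lengths apart
(`gall = host[:p] + foreign + host[p−m:p] + host[p:]` with microhomology
m ≥ 0, default 0), three endophyte genomes sequenced only in the gall
sample, two core-microbiome genomes sequenced in both, and uniform 150-bp
single-end reads at 16× depth with substitution-only errors at 0.1 % —
the published library design (150-bp SE, 16×) at desk scale. All
randomness flows from one seed; equal configs give byte-identical outputs.

Deliberate simplifications, and what they mean for the tests: no indel
errors (substitutions dominate on the emulated platform, and the
semiperfect-mapping contract stays crisp), uniform coverage without GC
bias, one clonal gall genome rather than a sub-clonal mixture of galls, and
a foreign pool constructed to share no 31-mer with the host, which makes
the truth set unambiguous. Passing recovery tests therefore demonstrate the
detection logic, not robustness to homologous integration, structural
noise, or mosaic tissue. Microbial genome size (30 kb, plasmid scale) and
counts are our choices for desk-scale runs; they set the exclusive-read
load, not the per-event signal.

Insertion donor segments are generated as separate pool sequences with zero
sample weight rather than slices of the sequenced endophyte genomes: if a
donor's k-mers also arrived via free-living genome reads, the de Bruijn
graph would branch at the insert boundary and truncate every hybrid contig
at ~k foreign bases, contradicting the one-contig-per-event behaviour the
pipeline is designed to detect. Endophyte reads still exercise the
gall-only taxon path.

## Evaluation conventions

Recovery matches retained calls to truth events greedily by distance
(nearest first, one-to-one, same chromosome, tolerance ±10 bp), so one call
recovers at most one event. A call counts as a false positive only when it
lies near *no* truth site: one event can legitimately assemble into separate
5′- and 3′-junction contigs, and the second fragment corroborates rather
than contradicts the call set. With no calls, precision is reported as 1.0 with
a `no_calls` flag rather than NaN. Report histograms use the published bin
edges (lengths (0,200], (200,500], (500,1000], (1000,2000], (2000,2501]
plus an overflow bin; support 3, 4–5, 6–9, 10–30, 31–95, >95 plus an
under-threshold bin for allowlisted calls) so bin counts always sum to the
number of summarized items.

At the default scale the full run (simulation + both samples + pipeline)
takes a few minutes on one CPU; the problem sizes above are the package's
own defaults and are what the test suite and `scripts/acceptance.py`
execute.

## Known limitations

- Reads whose on-reference span contains an N in every 31-window cannot be
  anchored and stay unmapped.
- The assembler has no bubble popping; clustered errors can fragment
  contigs and cost recall at low depth.
- The seeded aligner requires one exact 19-mer per true locus; anchors
  mutated more densely than that are invisible to it (and would fail the
  identity filter anyway).
- Chance matches at junction-adjacent bases can extend an anchor by a base
  or two; estimated sites are exact up to that jitter, hence the ±10 bp
  matching tolerance.
- In-silico PCR uses a mismatch budget (2) and 3′ clamp (5) typical of
  electronic PCR tools; annealing thermodynamics are not modelled.
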