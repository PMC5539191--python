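# Methods

## Model and assumptions

The package assumes the standard plastome architecture: a circular molecule
LSC + IR + SSC + revcomp(IR), present in total DNA at a per-base coverage
much higher than the nuclear background. Under uniform sequencing, k-mers
from the two IR copies collapse (they are exact reverse complements and are
counted canonically), so their frequency is exactly twice that of
single-copy plastome k-mers. Everything downstream leans on that single
structural fact: peak-pair detection, IR-aware merging, and the final
LSC/IR/SSC layout.

Canonical ("ordinal") k-mers use the middle-base rule: of a k-mer and its
reverse complement, the representative is the one whose middle nucleotide is
A or C. This requires odd k (enforced at configuration time) and gives each
k-mer exactly one representative, since complementing flips the middle base
between {A,C} and {G,T}. For k ≤ 31, k-mers are packed two bits per base
into uint64 with A=0 < C=1 < G=2 < T=3, so numeric order equals
lexicographic order and the sorted table is a sorted integer array; larger
k falls back to sorted string arrays, at string-processing speed.

## Peak detection

The published protocol chooses the k-mer frequency band by eye. The
automated detector smooths the volume histogram with a centred moving
average (window 5), takes local maxima above an error floor (by default the
first valley right of the f≈1 error peak), and returns the maxima pair
(p, q) with |q − 2p| ≤ 0.15·2p maximizing summed volume. The default band
[p/2, 3q/2], clipped above the error floor, spans both peaks as one
interval. The manual band (`--band MIN:MAX`) always takes precedence when
given.

Note the expected location of the SC mode: at read length L, k-mer size k
and error rate e, per-base coverage c yields a k-mer coverage of roughly
c·(L−k+1)/L·(1−e)^k — at the toy conditions (c=100, L=100, k=31, e=0.01)
about 51, not 100. The detector is agnostic to this; only the 2× relation
matters.

## Assembly

The internal assembler is a node-centric De Bruijn graph on canonical
K-mers:

- **Coverage cutoff.** K-mers below `min_edge_coverage` (default 3) are
  dropped, plus an adaptive cutoff at 10% of the volume-weighted mode of
  the solid-coverage distribution. The adaptive term removes recurrent
  sequencing errors at high depth (at 100×, an identical error at one
  position recurs ≥3 times with appreciable probability); setting
  `min_edge_coverage=1` disables it for exactness-sensitive uses.
- **Unitigs.** Maximal unambiguous paths (unique right extension whose
  target has a unique left extension), walked in sorted canonical order for
  determinism. A single clean cycle is emitted as a circular assembly.
- **Simplification.** Up to three rounds of removing dead-end tips shorter
  than 2K and popping bubbles (unitigs with identical external adjacency on
  both ends; the best-covered member is kept).
- **Paired scaffolding.** Contigs linked by ≥ `min_links` (default 3) pairs
  are joined with an N-run only when the second-ranked orientation has
  noise-level support — a repeat contig such as the IR links its neighbours
  in two orientations at once and must not be joined through.

SOAPdenovo-style external assemblers can be substituted via
`sweep_assemble`'s `assemble_fn`; a failing adapter invocation skips that
(batch, K) pair rather than aborting the sweep.

## Overlap merging and the inverted repeat

`overlap_merge` merges scaffold ends sharing exact overlaps
(≥ `min_overlap`, default 50; a mismatch budget is available but the first
12 junction bases must seed exactly), longest overlap first, each end used
at most once; a scaffold whose end overlaps its own start closes into a
circle. Two IR-specific behaviours:

- A contig whose **both** ends each overlap two partners is the collapsed
  IR: it is duplicated (chains orient instances freely) so all four
  junctions can be made, which is how {LSC, IR, SSC} closes into the
  circle.
- A large overlap between the reverse-complement *arms* of the two IR
  copies can out-rank the true junctions and orphan a single-copy contig.
  If the greedy pass does not produce a single circle, a second pass
  excludes same-side (L–L/R–R) records whose ends are both contested, and
  the better outcome (circular, then fewer scaffolds) is kept. The greedy
  longest-first rule and this arbitration are design choices; the tie-break
  order is documented in the code and deterministic.

IR detection on a finished circle seeds anti-diagonal runs of shared
25-mers between the doubled sequence and its reverse complement, extends
them maximally, and keeps the longest disjoint pair (minimum length 1 kb by
default, 500 bp in the toy profile). Maximal extension can overshoot a
constructed boundary by a base or two when flanking bases happen to
complement; consumers allow that slack. SSC length 0 (IR expansion) is
tolerated. The relative orientation of SSC vs LSC is not resolvable from
short reads; layouts emit both configurations (`two_circular`) or a
seeded choice (`one_circular`).

## Read mapping

Stages 4–5 use an exact-k-mer-seeded, ungapped mapper: canonical 31-mer
seeds at four positions per read vote for (scaffold, start, strand)
placements; the best placement by verified matches is reported with clipped
overhang lengths at scaffold ends. Ungapped extension is valid because the
simulator's error model is substitution-only; with real indel-bearing data
an external SAM-producing aligner should be preferred upstream.

## Stage orchestration

Stage 3 accepts only strict improvements under the active ranking mode and
stops on circularity, no improvement, or the iteration limit (default 10).
"Reads that extend outside the gaps" in stage 4 is interpreted as reads
overhanging scaffold ends plus mates of reads anchored within `end_window`
(default 600 bp) of an end and pointing outward; each end's set is
assembled separately across the K sweep. After the iteration loop a
scaffold-end connectivity matrix is built from read pairs whose mates point
out of different ends, and ends with ≥ `min_links` support are bridged with
`gap_n` = 100 N's (a fixed run: gap lengths are not estimated, keeping
outputs deterministic). Stage 5 filters read pairs positively (≥1 k-mer
from the 500 bp gap flanks, either mate) then negatively (no k-mer from the
non-context assembly regions, either mate); candidate closures must merge
with both flanks at ≥ `min_overlap`, and the shortest qualifying closure is
spliced in, which provably leaves all bases outside the gap contexts
untouched. Stage-3 read re-selection draws from the full raw dataset each
iteration (not the previous subset): the stage-2 subset can carry
band-collision contamination that re-selection against a clean assembly
should be free to drop.

## Simulator

`simulate` generates uniform paired-end reads (default 100 bp, insert
300 ± 30) from the plastome circle (positions wrap) and a random nuclear
background, with substitution errors only and origin-labelled read ids.
Study-condition defaults — plastome coverage 100×, nuclear 100 kb at 2×,
error 1% — are what the tests and the acceptance script use. What it does
*not* emulate: indels, quality-score structure, GC coverage bias (except
via the explicit `coverage_hole`, which zeroes sampling over an interval
and is used to show that a genuinely uncovered gap persists), PCR
duplicates, or organelle-to-nucleus transfers. Passing tests therefore
demonstrate the method's logic under its own model, not performance on real
Illumina libraries.

## Problem sizes and profiles

Protocol-scale defaults (k=31; K 63..99 odd; 100,000-pair batches with
100,000 increments; 500 bp flanks; 1000-read gap batches) are the package
defaults. The test/example profile (`toy_config`) scales the sweep to a
34 kb plastome: K ∈ {21, 31}, batches 5000/5000, merge overlap 30 (= K−1
at K=31, the exact overlap adjacent unitigs share), IR minimum 500 bp,
sanity range 15–45 kb. Two K values and four nested batches exercise the
same sweep/ranking machinery as the full grid while keeping a complete run
near ten seconds. The acceptance script runs five independent end-to-end
replicates.

## Known limitations

- Homology filtering is k-mer containment against a user-supplied
  reference (threshold 0.2), not BLAST; divergent chloroplasts may need the
  threshold lowered further, and without a reference the filter is off.
- The mapper and merger assume substitution-level divergence; indel-rich
  data will clip or fragment.
- K > 31 uses the string-based counting path, which is correct but slow at
  scale; counting tables for the selection machinery are limited to the
  encoded path's k ≤ 31 in practice.
- Heterzygosity and mitochondrial peaks are out of scope; a mitochondrial
  band falling inside the chloroplast band would co-select reads.
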