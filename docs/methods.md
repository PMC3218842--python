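# Methods

This note documents the models, estimators and numerical choices behind
hydroxyscan, the defaults that matter, and what the bundled synthetic study
does and does not demonstrate about real data.

## Coordinates and read processing

All intervals are 0-based half-open (BED convention); every writer and
reader declares this and GFF-style inputs must be shifted at the boundary.
Reads arrive as aligned intervals — base-calling, trimming and alignment
are upstream concerns, and any read-length trimming is assumed already
applied to the alignments.

Duplicate collapse keys on (chrom, start, end, strand) by default: a read
at the same coordinates on the opposite strand marks the other end of a
different fragment and is biologically distinct. The convention is
switchable (`strand_aware=False`) because published pipelines vary on this
point. Reads are the sequenced ends of fragments, so a plus-strand read
[s, e) is extended to [s, s + f) and a minus-strand read to [e − f, e),
clamped to the chromosome, with f the library's average fragment size.
No fragment-size estimate ships with aligned intervals, so f defaults to
200 bp (a typical sonicated ChIP/DIP library) and is configurable
everywhere it appears.

Density tracks are per-base counts of covering extended fragments divided
by (library size / 10⁶): reads/bp/million uniquely mapping reads. The
total track mass therefore equals total extended-fragment bp over library
size in millions, which the tests assert to 1e-9 relative tolerance.
Tracks are written as bedGraph with equal-value runs merged.

## Island calling

A deliberately simple SICER-flavoured caller:

- **window** 200 bp, **gap** 600 bp (the canonical SICER defaults; the gap
  must be a multiple of the window);
- window eligibility at ≥ 2 IP fragments (fragment = extended read,
  assigned to the single window containing its midpoint, so overlapping
  windows never double-count);
- eligible windows at most `gap` bp apart merge into candidate islands;
- island score: upper-tail Poisson probability of the island's IP count at
  rate λ = max(control_count, span_expectation, 1) × (N_IP / N_control);
- Benjamini–Hochberg across all islands of the (experiment, control) run;
- consensus: base-pair-wise intersection of the q < 0.05 island sets, first
  across the two controls within an experiment, then across the two
  experiments, with book-ended pieces merged.

The λ floor deserves a note. Candidate islands are *selected* for locally
high IP counts, so their null p-values are far from uniform, and a floor of
max(control, 1) alone lets BH cascade: thousands of weak two-window
islands with control counts of 0–1 become "significant" and the consensus
false-positive rate explodes (we measured ~70% on the standard synthetic
study). Flooring λ additionally at the island span's genome-wide expected
control count — what a uniform control library would put there — restores
conservativeness: measured sensitivity stays ≥ 98% while false positives
drop to ≤ 2%. The absolute floor of one read still guards the zero-control
degenerate case.

Consensus-by-intersection makes the operation symmetric in both controls
and both experiments (swapping either leaves the base-pair set unchanged)
and monotone in the FDR threshold: lowering the FDR removes whole islands
and can only shrink the consensus.

## Metaprofiles

Per bin the statistic is the mean fraction of bin bases covered by ≥ 1
region — bounded in [0, 1], invariant to region order and to splitting a
region at interior points. A midpoint-count estimator (regions/bp) is
available behind a flag for users who prefer peak-count semantics.

Gene bodies are length-normalised into 50 bins (fractional bin edges; genes
shorter than 50 bp per bin are handled by continuous-coordinate coverage,
no error); flanks are fixed 300-bp bins over ±15 kb by default. The flank
extent and stratum count are free choices: 15 kb shows both the promoter
dip and the body signal at typical gene sizes, and 5 expression strata is
the common quantile layout. Minus-strand genes are flipped so the TSS is
always left. Bins reaching past a chromosome end count as uncovered over
their full width.

Smoothing is the ±2-bin moving average. A truncated window renormalised
per-row preserves constants but not the profile mean; renormalised per
column it preserves the mean but not constants. We Sinkhorn-balance the
banded matrix to doubly stochastic, which preserves both exactly (to the
1e-13 iteration tolerance): interior bins get exactly the 1/5 five-point
weights, and only the four bins at each end deviate.

Expression strata rank genes by RPKM descending, ties broken by gene id,
split into near-equal groups (sizes differ by ≤ 1); genes missing from the
expression table are dropped and counted.

## Overlap enrichment and gene tests

The null redraws the region set with the exact length multiset: for each
interval, a chromosome is drawn with probability proportional to its length
among chromosomes that fit it, and the start is uniform over valid
positions; placements may overlap each other. A mask BED can exclude
regions (e.g. assembly gaps) from placement; the toy genome has none, so
the default is no mask. The overlap statistic is the fraction of regions
with ≥ 1 bp overlap with the feature set (the fraction-of-features variant
is exposed as a mode). Besides the null mean ± sd of the study design
(100 draws), we report z = (obs − mean)/sd and the +1-corrected empirical
p = (1 + #{null ≥ obs})/(n_perm + 1), the standard conservative estimator,
so significance is defined even at 100 draws (p floor 1/101).

Closest-gene assignment minimises the distance from any region base to a
gene TSS (0 if the TSS falls inside the region), capped at 100 kb; ties go
to the lexicographically smallest gene id. Cell-specific genes are those
with RPKM ≥ 0.5 in the cell of interest and RPKM = 0 in the comparison
cell, boundaries inclusive. Their region-overlap excess over all genes is
tested with two-sided Fisher's exact on the {specific, other} ×
{overlap, none} table, using the gene *body* for overlap (promoter-based
overlap is a caller-side choice we did not take); degenerate margins report
p = 1 with a flag rather than an error.

## Sequence composition

Base frequencies are pooled per offset across regions on the Watson strand,
anchored at the region start (5'), end − 1 (3') or midpoint. Regions are
unstranded, so "5'" means the lower coordinate and the Watson strand is
always the reference strand. Anchors near a chromosome edge contribute
only in-bounds offsets; the per-offset denominator tracks this, and N bases
are excluded from numerator and denominator and reported separately.
GC-skew is |G−C|/(G+C) — with the signed variant (G−C)/(G+C) for
directional questions — computed from *pooled* window counts (width 100 bp,
truncated at profile ends) rather than averaged per-region ratios, which is
stabler for short regions; a per-region option exists. G + C = 0 yields
skew 0 with an explicit undefined flag.

CpG counting is plain CG-dinucleotide counting on the given strand
(occurrences cannot overlap); the four bundled dot-blot control oligos with
12/6/3/1 sites serve as worked examples.

Region classification is priority-ordered: genic (≥ 1 bp gene-body
overlap) before enhancer before other, so a region under both labels counts
as genic.

## EpiMark quantification

Given copy numbers for (BGT | mock) × (undigested | MspI | HpaII):
background B is the mean mock+MspI signal (fully cuttable DNA's residual
amplification — the paper-style "background signal" left undefined by the
assay description; a user constant can replace it), and

    hmc       = (copies[BGT, MspI] − B) / (copies[BGT, none] − B)
    resistant = (copies[·, HpaII]  − B) / (copies[·, none]  − B)
    mc        = resistant − hmc,   unmodified = 1 − resistant

HpaII is insensitive to glucosylation in this model, so whichever treatment
was digested with HpaII is used (averaged if both). Replicates are averaged
before the point estimate; per-fraction sds come from replicate-wise
recomputation. Negative intermediates are clamped to zero with a visible
flag and the fractions renormalised to sum to 1; a non-positive denominator
(background ≥ undigested signal) is an assay failure and raises. The
estimator is scale-invariant and satisfies hmc ≤ resistant after clamping.

## The synthetic study

The generator's defaults define the standard conditions used by the tests
and the acceptance script: 5 chromosomes × 10 Mb; 60 planted regions
(length 1500 ± 300 bp, floor 200); GC-skew segments of 6 kb covering 1.2%
of the genome with bias 0.2 (G and C probabilities 0.25(1 ± b), so the
expected signed skew inside a half-segment is ±b, flipping sign at the
segment midpoint); 70% of regions centred on skew-segment midpoints; four
libraries of exactly 2×10⁵ 50-bp reads with 8-fold IP enrichment (fragment
midpoints fall with density ∝ 8 inside regions, uniform outside; controls
uniform); 500 non-overlapping genes of 5–30 kb; 200 enhancers of 1 kb
(15% centred on regions), 120 TFBS (30% at regions), 150 histone-mark
regions (60% at enhancers); 15% hESC-specific genes drawn with 6-fold
weight for region-overlapping genes; and a 6-locus qPCR panel (baseline
1000 copies, background rate 0.05, lognormal noise CV 0.1, 3 replicates)
whose generative table is constructed so the EpiMark estimator inverts it
exactly at zero noise — the additive background residue appears in every
reaction, undigested ones included.

The genome size is the one free scale: it was chosen so that, at the fixed
library depth and 2-read window threshold, background windows are rare
enough (~13% eligible) that islands reflect local enrichment rather than
chaining into chromosome-scale blocks. All randomness derives from a
single seed through named child streams, so each generator is individually
reproducible and a regenerated dataset is byte-identical.

What the synthetic study does *not* emulate: mappability and assembly gaps,
CpG-island and chromatin-state structure, sequencing error, antibody
density preference, diploidy, and length/GC biases of real libraries.
Passing the planted-recovery criteria therefore demonstrates the
correctness of the statistics and the plumbing under the stated generative
model — not calling performance on real hmeDIP-seq data, where control
quality and mappability dominate.

## Problem sizes and determinism

The test suite and acceptance script run the full study at the standard
50-Mb scale (simulation ≈ 6 s, calling ≈ 6 s) and use reduced 2–4-Mb
genomes for unit-level checks; the permutation-uniformity property uses
200 replications of a 99-draw null. Every stochastic test fixes its seed;
hypothesis-based property tests are bounded and seeded through pytest's
derandomised defaults. Outputs carry a header with the seed and a hash of
the analysis-relevant configuration (output location excluded), and two
runs from the same seed produce byte-identical files apart from wall-clock
fields in the manifest.
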