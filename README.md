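# hydroxyscan

Genome-wide analysis of 5-hydroxymethylcytosine (5hmC) maps produced by
hmeDIP-seq — hydroxymethyl-DNA immunoprecipitation followed by sequencing.
The package takes deduplicated, uniquely-aligned reads from an IP library
and its two background controls (input DNA and a no-antibody mock IP),
calls consensus 5hmC regions across two independent antibody experiments,
and runs the downstream analyses that characterise where the mark sits:
metagene profiles stratified by expression, permutation-based overlap
enrichment against enhancers and histone marks, closest-gene and
cell-specific gene-set tests, Watson-strand GC-skew profiling, and
restriction-qPCR (EpiMark-style) quantification of absolute 5hmC levels.

It is written for epigenomics analysts who want each step of such a
pipeline as a tested, importable function, with a bundled synthetic-data
generator so the whole stack can be exercised — and its error rates
measured — without any external download.

## The model

**Island calling.** The genome is tiled into fixed windows (default 200 bp,
SICER's canonical choice). Reads are collapsed to unique
(chrom, start, end, strand) tuples and extended to the library's average
fragment size; each fragment is assigned to the window containing its
midpoint. Windows with ≥ 2 IP fragments are merged across gaps of up to
600 bp into candidate islands. An island with IP count *n* and control
count *c* over span *s* is scored by the upper-tail Poisson probability

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ n), X ~ Poisson(λ), λ = max(c, E[c | s], 1) · N_IP / N_ctl

where E[c | s] is the control library's genome-wide expectation for a span
of *s* bp (islands are selected for locally high IP counts, so the observed
control alone underestimates the background). Benjamini–Hochberg correction
runs across all islands of a run; a region enters the consensus only if
significant (q < 0.05) against *both* controls in *both* antibody
experiments, taken as the base-pair-wise intersection of the passing sets.

**Downstream statistics.** Overlap enrichment uses a matched permutation
null: the region set is redrawn 100 times with identical number and length
multiset, uniformly over the genome, giving a null mean ± sd, a z-score and
the +1-corrected empirical p. Metaprofiles report per-bin mean base-pair
coverage over scaled gene bodies (50 bins, 300-bp flank bins, ±2-bin
moving-average smoothing) or fixed windows around feature centres. GC-skew
is |G−C|/(G+C) (signed variant (G−C)/(G+C)) from pooled Watson-strand
counts in 100-bp sliding windows around region anchors. EpiMark
quantification inverts the glucosylation/MspI/HpaII copy-number
normalisation: hmc = (BGT·MspI − B)/(BGT·undigested − B) with background B
from the mock+MspI reaction.

## Worked example

```bash
python examples/02_call_regions.py
python examples/04_enrichment_and_genes.py
```

prints, for the standard synthetic study (50-Mb genome, 60 planted regions,
2×10⁵-read libraries at 8-fold IP enrichment, seed 1):

```
consensus regions: 60 (mean length 1943 bp)
sensitivity: 100.0% of planted regions recovered
false positives: 0.0% of called regions

enhancers: observed 50.0% vs null 1.0% ± 1.3%  z=38.4  p=0.010
histone marks: observed 23.3% vs null 0.9% ± 1.1%  z=20.0  p=0.010
closest gene: 56/60 regions within 100 kb of a TSS
hESC-specific genes: 10.7% overlap regions vs 3.4% of all genes  (Fisher p=0.0014)
```

Reading: the caller recovered every planted region with no false calls;
called regions overlap enhancers and histone-mark regions far above the
matched-random null (the permutation p is floored at 1/101); and genes
expressed only in the stem-cell line overlap 5hmC regions about three times
as often as genes at large — the planted cell-specificity signal. The other
examples (`examples/0*.py`) cover simulation, metaprofiles, GC-skew and
EpiMark quantification, one capability each.

A thin CLI mirrors the library:
`hydroxyscan {simulate, tracks, call, metaprofile, enrich, nearest-gene,
specific-genes, skew, epimark, run}` (exit codes: 0 ok, 2 usage, 3 data
error).

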