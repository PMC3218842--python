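"""Generate a small synthetic hmeDIP-seq study and look at its ground truth.

The generator plants GC-skewed segments in a toy genome, puts "true" 5hmC
regions preferentially inside them, and simulates two IP libraries (8-fold
read enrichment over the planted regions) plus uniform input and
no-antibody controls.
"""

from hydroxyscan import SyntheticConfig, simulate_dataset

config = SyntheticConfig(
    n_chroms=2, chrom_length=2_000_000, n_true_regions=8,
    skew_segment_fraction=0.015, depth=30_000,
    n_genes=80, n_enhancers=30, n_tfbs=15, n_histone_marks=20, seed=11,
)
dataset = simulate_dataset(config)

truth = dataset.truth
print(f"genome: {sum(dataset.genome.chrom_sizes.values()):,} bp "
      f"over {len(dataset.genome.chrom_sizes)} chromosomes")
print(f"planted 5hmC regions: {len(truth.regions)} "
      f"(mean {sum(len(r) for r in truth.regions)/len(truth.regions):.0f} bp)")
print(f"skew segments: {len(truth.skew_segments)}, genes: {len(truth.gene_models)}, "
      f"enhancers: {len(truth.enhancers)}")
for label, reads in dataset.libraries.items():
    print(f"library {label}: {len(reads):,} aligned 50-bp reads")
# Each library has exactly `depth` reads; the IP libraries concentrate
# read midpoints inside the planted regions, the controls are uniform.
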