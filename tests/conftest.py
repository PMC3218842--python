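"""Shared fixtures: synthetic datasets at two scales.

``small_dataset`` is a fast 2 x 300-kb genome used by most unit tests;
``default_dataset`` runs the generator at its standard study conditions
(50-Mb genome, 2e5-read libraries) and is shared, session-scoped, by the
recovery and skew analyses.
"""

from __future__ import annotations

import numpy as np
import pytest

from hydroxyscan import SyntheticConfig, simulate_dataset
from hydroxyscan.islands import CallerParams, call_islands, consensus_regions, window_counts
from hydroxyscan.reads import deduplicate, extend_reads


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_chroms=2,
        chrom_length=2_000_000,
        n_true_regions=8,
        skew_segment_fraction=0.015,
        depth=30_000,
        n_genes=80,
        n_enhancers=30,
        n_tfbs=15,
        n_histone_marks=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SyntheticConfig(seed=101))


def call_consensus(dataset, params: CallerParams = None):
    """Run the full calling stage on a synthetic dataset."""
    params = params or CallerParams()
    cfg = dataset.config
    sizes = dataset.genome.chrom_sizes
    counts, nreads = {}, {}
    for label, reads in dataset.libraries.items():
        deduped = deduplicate(reads)
        extended = extend_reads(deduped, cfg.fragment_size, sizes)
        counts[label] = window_counts(extended, params.window, sizes)
        nreads[label] = len(deduped)
    island_sets = {
        (e, c): call_islands(counts[e], counts[c], (nreads[e], nreads[c]), params, sizes, c)
        for e in ("ip_a", "ip_b")
        for c in ("input", "noab")
    }
    regions = consensus_regions(
        island_sets[("ip_a", "input")],
        island_sets[("ip_a", "noab")],
        island_sets[("ip_b", "input")],
        island_sets[("ip_b", "noab")],
        fdr=params.fdr,
    )
    return regions, island_sets


@pytest.fixture(scope="session")
def default_consensus(default_dataset):
    regions, island_sets = call_consensus(default_dataset)
    return regions, island_sets
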