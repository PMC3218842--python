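"""Synthetic-data generator: determinism, planted structure, closed forms."""

import numpy as np
import pandas as pd
import pytest

from hydroxyscan.intervals import GenomicInterval, overlaps_any
from hydroxyscan.reads import extend_reads
from hydroxyscan.synthetic import (
    SyntheticConfig,
    TruthSet,
    generate_genome,
    generate_truth,
    simulate_dataset,
    simulate_libraries,
    simulate_qpcr,
    write_dataset,
)


def _tiny(**kw):
    base = dict(
        n_chroms=2,
        chrom_length=500_000,
        n_true_regions=4,
        skew_segment_fraction=0.02,
        depth=5_000,
        n_genes=15,
        n_enhancers=8,
        n_tfbs=5,
        n_histone_marks=6,
        seed=1,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _tiny(n_genes=-1)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            _tiny(skew_segment_fraction=1.5)

    def test_fragment_vs_read_length(self):
        with pytest.raises(ValueError):
            _tiny(fragment_size=40, read_length=50)

    def test_zero_length_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            _tiny(chrom_length=0)


class TestGenerateGenome:
    def test_seed_determinism(self):
        cfg = _tiny()
        a_seq, a_sizes, a_seg = generate_genome(cfg)
        b_seq, b_sizes, b_seg = generate_genome(cfg)
        assert a_seq == b_seq and a_sizes == b_sizes and a_seg == b_seg

    def test_zero_skew_fraction_gives_no_segments(self):
        _, _, segments = generate_genome(_tiny(skew_segment_fraction=0.0))
        assert segments == []

    def test_segment_skew_matches_binomial_oracle(self):
        """bias 0.2, 10-kb segments: Watson (G-C)/(G+C) over the 5' half is
        positive and within 3 binomial sd of the bias; 3' half mirrored."""
        cfg = _tiny(skew_bias=0.2, skew_segment_length=10_000, skew_segment_fraction=0.05)
        sequences, _, segments = generate_genome(cfg)
        assert segments
        for seg in segments:
            mid = (seg.start + seg.end) // 2
            for half, sign in ((slice(seg.start, mid), +1), (slice(mid, seg.end), -1)):
                s = sequences[seg.chrom][half]
                g, c = s.count("G"), s.count("C")
                skew = (g - c) / (g + c)
                assert sign * skew > 0
                # skew = 2p-1 with p = P(G | G or C) = (1 + bias) / 2
                sd = 2 * np.sqrt(0.5 * (1 + 0.2) * 0.5 * (1 - 0.2) / (g + c))
                assert abs(skew - sign * 0.2) < 3 * sd

    def test_background_composition_symmetric(self):
        cfg = _tiny(skew_segment_fraction=0.0)
        sequences, _, _ = generate_genome(cfg)
        s = sequences["chr1"]
        g, c = s.count("G"), s.count("C")
        assert abs(g - c) < 3 * np.sqrt(g + c)


class TestGenerateTruth:
    def test_regions_within_bounds_and_named(self):
        cfg = _tiny()
        _, sizes, segments = generate_genome(cfg)
        truth = generate_truth(cfg, segments)
        assert len(truth.regions) == cfg.n_true_regions
        for r in truth.regions:
            assert 0 <= r.start < r.end <= sizes[r.chrom]

    def test_expression_table_specific_genes(self):
        cfg = _tiny(n_genes=100, specific_gene_fraction=0.2, chrom_length=2_000_000)
        _, _, segments = generate_genome(cfg)
        truth = generate_truth(cfg, segments)
        expr = truth.expression
        specific = expr[expr["hesc_specific"]]
        assert len(specific) == 20
        assert (specific["rpkm_hesc"] >= 0.5).all()
        assert (specific["rpkm_imr90"] == 0.0).all()

    def test_locus_fractions_valid(self):
        cfg = _tiny()
        _, _, segments = generate_genome(cfg)
        truth = generate_truth(cfg, segments)
        lf = truth.locus_fractions
        assert ((lf["hmc"] >= 0) & (lf["mc"] >= 0) & (lf["hmc"] + lf["mc"] <= 1)).all()


def _uniform_truth(regions):
    return TruthSet(
        regions=regions,
        skew_segments=[],
        gene_models=[],
        enhancers=[],
        tfbs=[],
        histone_marks=[],
        expression=pd.DataFrame({"gene_id": [], "rpkm_hesc": [], "rpkm_imr90": []}),
        locus_fractions=pd.DataFrame({"locus": [], "hmc": [], "mc": []}),
    )


class TestSimulateLibraries:
    def test_library_size_conservation_and_determinism(self):
        cfg = _tiny(depth=7_777)
        truth = _uniform_truth([GenomicInterval("chr1", 100_000, 110_000)])
        a = simulate_libraries(cfg, truth)
        b = simulate_libraries(cfg, truth)
        for lib_a, lib_b in zip(a, b):
            assert len(lib_a) == 7_777
            assert lib_a == lib_b

    def test_zero_depth_allowed(self):
        libs = simulate_libraries(_tiny(depth=0), _uniform_truth([]))
        assert all(lib == [] for lib in libs)

    def test_enrichment_below_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_libraries(_tiny(ip_enrichment=0.5), _uniform_truth([]))

    @staticmethod
    def _in_region_fraction(cfg, reads, region):
        ext = extend_reads(reads, cfg.fragment_size, cfg.chrom_sizes())
        mids = [(iv.chrom, iv.midpoint) for iv in ext]
        return np.mean(
            [c == region.chrom and region.start <= m < region.end for c, m in mids]
        )

    def test_null_enrichment_uniform(self):
        """ip_enrichment=1: in-region read density equals background."""
        cfg = _tiny(n_chroms=1, chrom_length=1_000_000, depth=50_000, ip_enrichment=1.0)
        region = GenomicInterval("chr1", 495_000, 505_000)  # 1% of genome
        ip, _, _ = simulate_libraries(cfg, _uniform_truth([region]))
        frac = self._in_region_fraction(cfg, ip, region)
        p = 0.01
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / cfg.depth)

    def test_mixture_expectation_closed_form(self):
        """ip_enrichment=10 over 1% of the genome: in-region read fraction
        is 10*0.01 / (10*0.01 + 0.99)."""
        cfg = _tiny(n_chroms=1, chrom_length=1_000_000, depth=50_000, ip_enrichment=10.0)
        region = GenomicInterval("chr1", 495_000, 505_000)
        ip, inp, _ = simulate_libraries(cfg, _uniform_truth([region]))
        p = 10 * 0.01 / (10 * 0.01 + 0.99)
        frac = self._in_region_fraction(cfg, ip, region)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / cfg.depth)
        # the matched input stays uniform
        frac_inp = self._in_region_fraction(cfg, inp, region)
        assert abs(frac_inp - 0.01) < 3 * np.sqrt(0.01 * 0.99 / cfg.depth)

    def test_reads_have_read_length_and_strands(self):
        cfg = _tiny(depth=500)
        ip, _, _ = simulate_libraries(cfg, _uniform_truth([]))
        assert {len(r) for r in ip} == {cfg.read_length}
        assert {r.strand for r in ip} == {"+", "-"}


class TestSimulateQpcr:
    def test_determinism(self):
        lf = pd.DataFrame({"locus": ["a"], "hmc": [0.2], "mc": [0.3]})
        cfg = _tiny(qpcr_noise_cv=0.2)
        pd.testing.assert_frame_equal(simulate_qpcr(lf, cfg), simulate_qpcr(lf, cfg))

    def test_invalid_fractions_rejected(self):
        lf = pd.DataFrame({"locus": ["a"], "hmc": [0.8], "mc": [0.5]})
        with pytest.raises(ValueError):
            simulate_qpcr(lf, _tiny())

    def test_noise_cv_calibrated(self):
        lf = pd.DataFrame({"locus": [f"l{i}" for i in range(500)], "hmc": 0.0, "mc": 0.0})
        cfg = _tiny(qpcr_noise_cv=0.1, qpcr_replicates=1)
        q = simulate_qpcr(lf, cfg)
        undig = q[q["digestion"] == "none"]["copies"]
        assert abs(undig.std() / undig.mean() - 0.1) < 0.02


def test_full_dataset_determinism_and_write(tmp_path):
    cfg = _tiny()
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    assert a.truth.regions == b.truth.regions
    assert a.libraries["ip_a"] == b.libraries["ip_a"]
    assert a.libraries["ip_a"] != a.libraries["ip_b"]  # independent experiments
    pd.testing.assert_frame_equal(a.qpcr, b.qpcr)

    paths = write_dataset(a, tmp_path / "out")
    for p in paths.values():
        assert p.exists()
    # byte-identical on re-write (end-to-end seed determinism)
    paths_b = write_dataset(b, tmp_path / "out2")
    for k in paths:
        assert paths[k].read_bytes() == paths_b[k].read_bytes()


def test_planted_regions_prefer_skew_segments(small_dataset):
    truth = small_dataset.truth
    frac = overlaps_any(truth.regions, truth.skew_segments).mean()
    expected = small_dataset.config.region_at_skew_fraction
    assert frac >= expected - 0.15
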