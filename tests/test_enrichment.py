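"""Permutation enrichment, closest genes and gene-set tests vs oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from hydroxyscan.enrichment import (
    closest_gene,
    gene_set_overlap_test,
    overlap_fraction,
    permutation_enrichment,
    random_matched_intervals,
    specific_gene_set,
)
from hydroxyscan.intervals import GenomicInterval
from hydroxyscan.metaprofile import GeneModel

SIZES = {"chr1": 1_000_000, "chr2": 500_000}


def _random_intervals(rng, n, span=900_000):
    return [
        GenomicInterval("chr1", int(s), int(s) + int(rng.integers(100, 2000)))
        for s in rng.integers(0, span, n)
    ]


class TestRandomMatchedIntervals:
    def test_length_multiset_preserved(self):
        rng = np.random.default_rng(0)
        template = _random_intervals(rng, 50)
        placed = random_matched_intervals(template, SIZES, rng)
        assert sorted(len(iv) for iv in placed) == sorted(len(iv) for iv in template)

    def test_same_seed_identical_placement(self):
        template = _random_intervals(np.random.default_rng(1), 20)
        a = random_matched_intervals(template, SIZES, np.random.default_rng(42))
        b = random_matched_intervals(template, SIZES, np.random.default_rng(42))
        assert a == b

    def test_start_uniformity_chi_square(self):
        """1-bp template on a 10-bp chromosome: starts uniform over 0..9."""
        rng = np.random.default_rng(2)
        template = [GenomicInterval("c", 0, 1)] * 100_000
        placed = random_matched_intervals(template, {"c": 10}, rng)
        counts = np.bincount([iv.start for iv in placed], minlength=10)
        chi2, p = stats.chisquare(counts)
        assert p > 0.001

    def test_oversized_template_rejected(self):
        with pytest.raises(ValueError):
            random_matched_intervals([GenomicInterval("c", 0, 2_000_000)], SIZES, np.random.default_rng(0))


class TestOverlapFraction:
    def test_saturated_and_disjoint(self):
        a = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 5000, 6000)]
        genome_wide = [GenomicInterval("chr1", 0, 1_000_000)]
        assert overlap_fraction(a, genome_wide) == 1.0
        assert overlap_fraction(a, [GenomicInterval("chr1", 300, 400)]) == 0.0
        with pytest.raises(ValueError):
            overlap_fraction([], genome_wide)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(3)
        a = _random_intervals(rng, 80)
        b = _random_intervals(rng, 80)
        oracle = (
            sum(any(x.start < y.end and y.start < x.end for y in b) for x in a) / len(a)
        )
        assert overlap_fraction(a, b) == pytest.approx(oracle)
        oracle_b = (
            sum(any(x.start < y.end and y.start < x.end for x in a) for y in b) / len(b)
        )
        assert overlap_fraction(a, b, mode="fraction_of_b_with_hit") == pytest.approx(oracle_b)


class TestPermutationEnrichment:
    def test_saturated_null(self):
        regions = [GenomicInterval("chr1", 1000, 2000)]
        genome_wide = [GenomicInterval(c, 0, L) for c, L in SIZES.items()]
        res = permutation_enrichment(regions, genome_wide, SIZES, n_perm=20, seed=0)
        assert res.observed_overlap == 1.0 and res.null_mean == 1.0
        assert res.z_score == 0.0 and res.empirical_p == 1.0

    def test_null_hit_rate_matches_enumeration_oracle(self):
        """One 1-kb region vs a 100-kb feature on a 1-Mb chromosome: the
        exact null hit probability is (100000 + 999) / 999001."""
        sizes = {"c": 1_000_000}
        regions = [GenomicInterval("c", 500_000, 501_000)]
        feature = [GenomicInterval("c", 200_000, 300_000)]
        p_exact = (100_000 + 999) / 999_001
        n_perm = 10_000
        res = permutation_enrichment(regions, feature, sizes, n_perm=n_perm, seed=5)
        sd = math.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.null_mean - p_exact) < 3 * sd

    def test_maximal_enrichment_p_floor(self):
        regions = [GenomicInterval("chr1", 1000, 1100)]
        res = permutation_enrichment(regions, regions, SIZES, n_perm=99, seed=1)
        assert res.observed_overlap == 1.0
        assert res.empirical_p == pytest.approx(1 / 100)

    def test_empirical_p_uniform_under_null(self):
        """Regions drawn from the null give approximately uniform p."""
        sizes = {"c": 200_000}
        features = [GenomicInterval("c", int(s), int(s) + 3000) for s in range(0, 200_000, 10_000)]
        rng = np.random.default_rng(7)
        template = [
            GenomicInterval("c", 0, int(L)) for L in rng.integers(100, 500, 300)
        ]
        pvals = []
        for rep in range(200):
            null_regions = random_matched_intervals(template, sizes, rng)
            res = permutation_enrichment(null_regions, features, sizes, n_perm=99, seed=1000 + rep)
            pvals.append(res.empirical_p)
        assert min(pvals) >= 1 / 100
        # smooth the discrete p (support {k/100}) before comparing with U(0,1)
        jitter = np.random.default_rng(0).uniform(0, 1 / 100, 200)
        d, p = stats.kstest(np.array(pvals) - jitter, "uniform")
        assert p > 0.001

    def test_n_perm_validation(self):
        with pytest.raises(ValueError):
            permutation_enrichment(
                [GenomicInterval("chr1", 0, 10)], [], SIZES, n_perm=0
            )


class TestClosestGene:
    GENES = [
        GeneModel("chr1", 10_000, 20_000, "+", "alpha"),  # TSS 10000
        GeneModel("chr1", 40_000, 50_000, "-", "beta"),  # TSS 49999
        GeneModel("chr2", 5_000, 9_000, "+", "gamma"),
    ]

    def test_tss_inside_region(self):
        (a,) = closest_gene([GenomicInterval("chr1", 9_000, 11_000)], self.GENES)
        assert a.gene_id == "alpha" and a.tss_distance == 0

    def test_threshold_excludes_distant(self):
        (a,) = closest_gene([GenomicInterval("chr1", 200_000, 200_100)], self.GENES)
        assert a.gene_id is None and a.tss_distance is None

    def test_minus_strand_tss(self):
        (a,) = closest_gene([GenomicInterval("chr1", 52_000, 52_100)], self.GENES)
        assert a.gene_id == "beta" and a.tss_distance == 52_000 - 49_999

    def test_tie_breaks_lexicographically(self):
        genes = [
            GeneModel("chr1", 200, 300, "+", "zed"),
            GeneModel("chr1", 700, 800, "+", "ant"),  # both TSS 250 bp from region edge bases
        ]
        # region [400, 500): distance to TSS 200 is 200; to TSS 700 is 201
        genes = [
            GeneModel("chr1", 200, 300, "+", "zed"),
            GeneModel("chr1", 699, 800, "+", "ant"),
        ]
        (a,) = closest_gene([GenomicInterval("chr1", 400, 500)], genes)
        # both TSSs are 200 bp from the nearest region base
        assert a.tss_distance == 200 and a.gene_id == "ant"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        genes = [
            GeneModel("chr1", int(s), int(s) + 1000, "+" if rng.random() < 0.5 else "-", f"g{i:03d}")
            for i, s in enumerate(rng.integers(0, 900_000, 120))
        ]
        regions = _random_intervals(rng, 60)
        got = closest_gene(regions, genes, max_distance=100_000)
        for region, assignment in zip(regions, got):
            best = None
            for g in genes:
                tss = g.tss
                if tss < region.start:
                    d = region.start - tss
                elif tss > region.end - 1:
                    d = tss - (region.end - 1)
                else:
                    d = 0
                key = (d, g.gene_id)
                if best is None or key < best:
                    best = key
            if best[0] > 100_000:
                assert assignment.gene_id is None
            else:
                assert (assignment.tss_distance, assignment.gene_id) == best

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        genes = [
            GeneModel("chr1", int(s), int(s) + 500, "+", f"g{i}")
            for i, s in enumerate(rng.integers(0, 400_000, 30))
        ]
        regions = _random_intervals(rng, 20, span=400_000)
        base = closest_gene(regions, genes)
        shift = 17_000
        shifted = closest_gene(
            [iv.shifted(shift) for iv in regions],
            [GeneModel(g.chrom, g.tx_start + shift, g.tx_end + shift, g.strand, g.gene_id) for g in genes],
        )
        assert [(a.gene_id, a.tss_distance) for a in base] == [
            (a.gene_id, a.tss_distance) for a in shifted
        ]


class TestSpecificGeneSet:
    @pytest.mark.parametrize(
        "a,b,included",
        [(0.5, 0.0, True), (0.4, 0.0, False), (2.0, 0.1, False), (10.0, 0.0, True)],
    )
    def test_boundaries(self, a, b, included):
        selected, _ = specific_gene_set({"g": a}, {"g": b})
        assert ("g" in selected) is included

    def test_missing_genes_counted(self):
        selected, missing = specific_gene_set({"g1": 1.0, "g2": 1.0}, {"g1": 0.0})
        assert selected == {"g1"} and missing == 1


class TestGeneSetOverlapTest:
    def _genes(self, n):
        return [GeneModel("chr1", i * 1000, i * 1000 + 500, "+", f"g{i:02d}") for i in range(n)]

    def test_perfect_separation(self):
        """Table [[10,0],[0,10]]: two-sided Fisher p = 2 / C(20,10)."""
        genes = self._genes(20)
        special = {g.gene_id for g in genes[:10]}
        regions = [GenomicInterval("chr1", g.tx_start, g.tx_end) for g in genes[:10]]
        res = gene_set_overlap_test(special, genes, regions)
        assert res.table.tolist() == [[10, 0], [0, 10]]
        assert res.infinite_odds
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_identical_proportions_p_one(self):
        genes = self._genes(20)
        special = {g.gene_id for g in genes[:10]}
        # half of each group overlaps
        idx = list(range(0, 20, 2))
        regions = [GenomicInterval("chr1", genes[i].tx_start, genes[i].tx_end) for i in idx]
        res = gene_set_overlap_test(special, genes, regions)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_margin_flagged(self):
        genes = self._genes(10)
        res = gene_set_overlap_test(set(), genes, [])
        assert res.degenerate and res.p_value == 1.0

    def test_fisher_matches_hypergeometric_tail_oracle(self):
        """Two-sided Fisher p equals the sum of hypergeometric probabilities
        of tables at least as extreme, on random tables with margins <= 50."""
        rng = np.random.default_rng(6)
        for _ in range(60):
            n = int(rng.integers(4, 51))
            k = int(rng.integers(1, n))  # special genes
            m = int(rng.integers(1, n))  # overlapping genes
            a = int(rng.integers(max(0, k + m - n), min(k, m) + 1))
            table = [[a, k - a], [m - a, n - k - m + a]]
            _, p_scipy = stats.fisher_exact(table)
            # oracle: enumerate all tables with the same margins
            p_obs = stats.hypergeom.pmf(a, n, k, m)
            total = 0.0
            for x in range(max(0, k + m - n), min(k, m) + 1):
                px = stats.hypergeom.pmf(x, n, k, m)
                if px <= p_obs * (1 + 1e-9):
                    total += px
            assert p_scipy == pytest.approx(min(total, 1.0), rel=1e-7)

    def test_unknown_special_gene_rejected(self):
        with pytest.raises(ValueError):
            gene_set_overlap_test({"nope"}, self._genes(3), [])
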