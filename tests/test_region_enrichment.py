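import dataclasses

import numpy as np
import pytest
from scipy import stats

from te_karyoscan.annotations_io import AnnotationError, GenomicInterval
from te_karyoscan.region_enrichment import (
    RegionSet,
    count_overlaps,
    intragenic_overlap_test,
    permutation_enrichment,
    upstream_regions,
)

from conftest import make_copies, make_genes


def brute_force_overlaps(regions, copies, count_once):
    """O(n*m) all-pairs oracle."""
    total = 0
    for iv in regions.regions.values():
        hits = sum(1 for c in copies if iv.overlaps(c.interval))
        total += (hits > 0) if count_once else hits
    return int(total)


class TestUpstreamRegions:
    def test_plus_strand_region_precedes_tss(self):
        genes = make_genes([("g", "chr1", 5000, 8000, "+")])
        r = upstream_regions(genes).regions["g"]
        assert (r.start, r.end) == (2000, 5000)

    def test_minus_strand_region_follows_gene_end(self):
        genes = make_genes([("g", "chr1", 5000, 8000, "-")])
        r = upstream_regions(genes).regions["g"]
        assert (r.start, r.end) == (8000, 11000)

    def test_clipped_at_chromosome_start(self):
        genes = make_genes([("g", "chr1", 1000, 4000, "+")])
        r = upstream_regions(genes).regions["g"]
        assert (r.start, r.end) == (0, 1000)

    def test_clipped_at_chromosome_end_when_lengths_given(self):
        genes = make_genes([("g", "chr1", 5000, 8000, "-")])
        r = upstream_regions(genes, chrom_lengths={"chr1": 9000}).regions["g"]
        assert (r.start, r.end) == (8000, 9000)

    def test_non_positive_span_rejected(self):
        with pytest.raises(AnnotationError, match="span"):
            upstream_regions(make_genes([("g", "chr1", 0, 10, "+")]), span=0)


class TestCountOverlaps:
    def test_count_once_collapses_multiple_hits(self):
        regions = RegionSet({"r": GenomicInterval("chr1", 100, 400)})
        copies = make_copies(
            [("chr1", 120, 140, "+", "A"), ("chr1", 200, 220, "-", "A"),
             ("chr1", 350, 450, "+", "B")]
        )
        assert count_overlaps(regions, copies, count_once=True) == 1
        assert count_overlaps(regions, copies, count_once=False) == 3

    def test_half_open_abutment_is_no_overlap(self):
        regions = RegionSet({"r": GenomicInterval("chr1", 100, 200)})
        copies = make_copies([("chr1", 200, 300, "+", "A")])
        assert count_overlaps(regions, copies, count_once=True) == 0

    @pytest.mark.parametrize("count_once", [True, False])
    def test_matches_brute_force_oracle(self, count_once):
        rng = np.random.default_rng(5)
        regions = RegionSet(
            {
                f"r{i}": GenomicInterval(
                    f"chr{rng.integers(1, 4)}", s := int(rng.integers(0, 10000)),
                    s + int(rng.integers(1, 500)),
                )
                for i in range(40)
            }
        )
        copies = make_copies(
            [
                (
                    f"chr{rng.integers(1, 4)}",
                    s := int(rng.integers(0, 10000)),
                    s + int(rng.integers(1, 300)),
                    "+" if rng.random() < 0.5 else "-",
                    "S",
                )
                for _ in range(60)
            ]
        )
        assert count_overlaps(regions, copies, count_once) == brute_force_overlaps(
            regions, copies, count_once
        )

    def test_translation_invariance(self):
        regions = RegionSet(
            {"a": GenomicInterval("chr1", 100, 300), "b": GenomicInterval("chr1", 900, 1200)}
        )
        copies = make_copies([("chr1", 250, 350, "+", "S"), ("chr1", 1100, 1150, "-", "S")])
        shift = 7777
        regions2 = RegionSet(
            {k: GenomicInterval(v.chrom, v.start + shift, v.end + shift)
             for k, v in regions.regions.items()}
        )
        copies2 = make_copies(
            [(c.interval.chrom, c.interval.start + shift, c.interval.end + shift,
              c.interval.strand, c.subfamily) for c in copies]
        )
        for once in (True, False):
            assert count_overlaps(regions, copies, once) == count_overlaps(
                regions2, copies2, once
            )

    def test_disjoint_chromosome_naming_rejected(self):
        regions = RegionSet({"r": GenomicInterval("chr1", 0, 100)})
        copies = make_copies([("1", 0, 100, "+", "A")])
        with pytest.raises(AnnotationError, match="naming"):
            count_overlaps(regions, copies)


class TestPermutationTest:
    def universe_with_copies(self, n_regions=60, seed=0):
        rng = np.random.default_rng(seed)
        universe = RegionSet(
            {
                f"g{i}": GenomicInterval("chr1", i * 5000, i * 5000 + 3000)
                for i in range(n_regions)
            },
            universe=True,
        )
        offsets = rng.integers(0, 4500, size=n_regions // 2)
        copies = make_copies(
            [
                ("chr1", i * 5000 + int(o), i * 5000 + int(o) + 200, "+", "S")
                for i, o in enumerate(offsets)
            ]
        )
        return universe, copies

    def test_selected_equals_universe_gives_p_one(self):
        universe, copies = self.universe_with_copies()
        res = permutation_enrichment(universe, universe, copies, n_perm=200, seed=1)
        assert res.p_empirical == 1.0

    def test_planted_signal_detected_at_floor(self):
        # copies only inside the selected regions, universe 10x larger
        universe = RegionSet(
            {f"g{i}": GenomicInterval("chr1", i * 5000, i * 5000 + 3000) for i in range(100)},
            universe=True,
        )
        selected = universe.subset([f"g{i}" for i in range(10)])
        copies = make_copies(
            [("chr1", i * 5000 + 100, i * 5000 + 400, "+", "S") for i in range(10)]
        )
        res = permutation_enrichment(selected, universe, copies, n_perm=500, seed=3)
        assert res.alternative == "greater"
        assert res.observed == 10
        assert res.p_empirical <= 3 / 501

    def test_seed_determinism_bit_for_bit(self):
        universe, copies = self.universe_with_copies()
        selected = universe.subset([f"g{i}" for i in range(15)])
        r1 = permutation_enrichment(selected, universe, copies, n_perm=300, seed=9)
        r2 = permutation_enrichment(selected, universe, copies, n_perm=300, seed=9)
        assert dataclasses.asdict(r1) == dataclasses.asdict(r2)

    def test_empirical_p_lower_bound(self):
        universe, copies = self.universe_with_copies()
        selected = universe.subset([f"g{i}" for i in range(5)])
        res = permutation_enrichment(selected, universe, copies, n_perm=100, seed=2)
        assert res.p_empirical >= 1 / 101

    def test_selection_outside_universe_rejected(self):
        universe, copies = self.universe_with_copies()
        rogue = RegionSet({"x": GenomicInterval("chr1", 0, 10)})
        with pytest.raises(AnnotationError, match="subset"):
            permutation_enrichment(rogue, universe, copies, n_perm=10, seed=0)


class TestIntragenicOverlap:
    def test_strand_mismatch_not_contained(self):
        genes = make_genes([("g", "chr1", 1000, 5000, "+")])
        copies = make_copies([("chr1", 2000, 2300, "-", "S")])
        res = intragenic_overlap_test(genes, copies, genes, strand_aware=True)
        assert res.n_selected_containing == 0
        res2 = intragenic_overlap_test(genes, copies, genes, strand_aware=False)
        assert res2.n_selected_containing == 1

    def test_fixture_matches_binomial_oracle(self):
        # 10 of 100 genes contain a copy; 4 of the 10 selected genes do
        genes = []
        copies = []
        for i in range(100):
            start = i * 10000
            genes.append((f"g{i}", "chr1", start, start + 2000, "+"))
            if i in {0, 1, 2, 3, 20, 30, 40, 50, 60, 70}:  # contained copies
                copies.append(("chr1", start + 500, start + 800, "+", "S"))
        gene_set = make_genes(genes)
        selected = gene_set.subset([f"g{i}" for i in range(10)])  # contains 0..3
        res = intragenic_overlap_test(selected, make_copies(copies), gene_set)
        assert (res.n_selected, res.n_selected_containing) == (10, 4)
        assert np.isclose(res.expected_prop, 0.10)
        pmf = stats.binom.pmf(np.arange(11), 10, 0.10)
        oracle = pmf[pmf <= pmf[4] * (1 + 1e-12)].sum()
        assert np.isclose(res.p, oracle, rtol=1e-9)

    def test_selection_equal_to_all_genes_gives_p_one(self):
        genes = make_genes(
            [(f"g{i}", "chr1", i * 1000, i * 1000 + 500, "+") for i in range(20)]
        )
        copies = make_copies([("chr1", 100, 200, "+", "S")])
        res = intragenic_overlap_test(genes, copies, genes)
        assert res.observed_prop == res.expected_prop
        assert res.p == 1.0

    def test_no_background_overlap_skips_test(self):
        genes = make_genes([("g", "chr1", 0, 100, "+")])
        copies = make_copies([("chr2", 0, 100, "+", "S")])
        res = intragenic_overlap_test(genes, copies, genes)
        assert res.status == "no_background_overlap"
        assert res.p is None
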