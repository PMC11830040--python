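"""Tiling, arcsine-Z aggregation, peak assignment and composition tests."""

import math
from itertools import product

import numpy as np
import pytest

from cpgdyad import (
    GenomicInterval,
    NarrowPeak,
    SiteCounts,
    aggregate_modification,
    assign_peaks,
    composition_test,
    cross_method_correlation,
    peak_tile_concordance,
    tile_genome,
)
from cpgdyad.enrichment import primary_feature_of_tiles
from cpgdyad.simulate import simulate_peaks_for_scores


def _interval_sites(iv, n_cpg, n_mod_per_site, depth=10):
    """n_cpg forward-strand sites in iv, each depth `depth` with n_mod 5hmC."""
    step = max(2, len(iv) // max(n_cpg, 1))
    return [
        SiteCounts(iv.chrom, iv.start + i * step, "+",
                   depth - n_mod_per_site, 0, n_mod_per_site)
        for i in range(n_cpg)
    ]


class TestTileGenome:
    def test_partial_final_tile(self):
        tiles = tile_genome({"chr1": 1200}, width_bp=500)
        assert [(t.start, t.end) for t in tiles] == [(0, 500), (500, 1000), (1000, 1200)]
        assert tiles[-1].feature_class == "partial_tile"

    def test_exact_fit_single_tile(self):
        (tile,) = tile_genome({"chr1": 500})
        assert (tile.start, tile.end) == (0, 500)
        assert tile.feature_class is None

    def test_disjoint_cover(self):
        tiles = tile_genome({"chr1": 2100, "chr2": 900}, width_bp=400)
        by_chrom = {}
        for t in tiles:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, size in (("chr1", 2100), ("chr2", 900)):
            ts = by_chrom[chrom]
            assert ts[0].start == 0 and ts[-1].end == size
            assert all(a.end == b.start for a, b in zip(ts, ts[1:]))


class TestAggregate:
    def _records(self, proportions, n_cpg=12, depth=100):
        tiles = tile_genome({"chr1": 500 * len(proportions)}, width_bp=500)
        sites = []
        for t, p in zip(tiles, proportions):
            sites.extend(_interval_sites(t, n_cpg, int(round(p * depth)), depth))
        return aggregate_modification(sites, tiles, target="5hmC", min_cpg=10)

    def test_z_standardization(self):
        records = self._records([0.0, 0.1, 0.2, 0.5, 0.9])
        zs = np.array([r.z for r in records])
        assert zs.mean() == pytest.approx(0.0, abs=1e-12)
        assert zs.std() == pytest.approx(1.0, abs=1e-12)

    def test_equal_proportions_zero_sd_rule(self):
        records = self._records([0.3, 0.3, 0.3])
        assert all(r.z == 0.0 for r in records)

    def test_arcsine_values_and_ranking(self):
        records = self._records([0.0, 0.25, 1.0])
        arcs = [r.arcsine_value for r in records]
        assert arcs == pytest.approx([0.0, math.pi / 6, math.pi / 2])
        assert max(records, key=lambda r: r.z).proportion == 1.0

    def test_min_cpg_filter_applied_before_z(self):
        tiles = tile_genome({"chr1": 1500}, width_bp=500)
        sites = _interval_sites(tiles[0], 9, 90, 100)      # 9 CpGs: dropped
        sites += _interval_sites(tiles[1], 12, 10, 100)
        sites += _interval_sites(tiles[2], 12, 20, 100)
        records = aggregate_modification(sites, tiles, min_cpg=10)
        assert len(records) == 2
        assert all(r.n_cpg_sites >= 10 for r in records)
        # z computed over the two retained records only
        assert sorted(r.z for r in records) == pytest.approx([-1.0, 1.0])

    def test_monotone_transform_preserves_ranking(self, rng):
        props = rng.uniform(0, 1, size=30)
        records = self._records(list(props))
        by_prop = sorted(records, key=lambda r: r.proportion)
        by_z = sorted(records, key=lambda r: r.z)
        assert [r.interval.start for r in by_prop] == [r.interval.start for r in by_z]

    def test_all_dropped_errors(self):
        tiles = tile_genome({"chr1": 500})
        sites = _interval_sites(tiles[0], 3, 1)
        with pytest.raises(ValueError, match="dropped"):
            aggregate_modification(sites, tiles, min_cpg=10)


class TestAssignPeaks:
    TILES = tile_genome({"chr1": 2000}, width_bp=500)

    def _peak(self, start, end):
        return NarrowPeak(GenomicInterval("chr1", start, end), (end - start) // 2)

    def test_fully_inside(self):
        assigned, unassigned = assign_peaks([self._peak(100, 200)], self.TILES)
        assert assigned[0].start == 0 and not unassigned

    def test_60_40_split_assigned_to_larger(self):
        # 100 bp peak: 60 bp in tile [0,500), 40 bp in tile [500,1000)
        assigned, _ = assign_peaks([self._peak(440, 540)], self.TILES)
        assert assigned[0].start == 0

    def test_45_35_20_split_dropped(self):
        # 1000 bp peak over three tiles: overlaps 450/500/50 -> 50% exactly?
        # construct 45/35/20: peak [275, 1275) length 1000 ->
        # overlaps: [275,500)=225 (22.5%), [500,1000)=500 (50%) ... use a
        # peak whose best overlap is 45%: length 1000, [50, 1050):
        # overlaps 450 (45%), 500 (50%) -- still 50. Use tiles of 400:
        tiles = tile_genome({"chr1": 2000}, width_bp=400)
        peak = self._peak(40, 1040)  # overlaps 360 (36%), 400 (40%), 240 (24%)
        assigned, unassigned = assign_peaks([peak], tiles)
        assert not assigned and unassigned == [0]

    def test_tie_broken_to_lower_coordinate(self):
        assigned, _ = assign_peaks([self._peak(450, 550)], self.TILES)
        assert assigned[0].start == 0

    def test_overlap_conserved_across_tiles(self):
        peak = self._peak(300, 1300)
        total = sum(peak.interval.overlap(t) for t in self.TILES)
        assert total == len(peak.interval)


class TestConcordance:
    def _records(self, zs):
        tiles = tile_genome({"chr1": 500 * len(zs)}, width_bp=500)
        sites = []
        # proportions chosen monotone in z to give the wanted sign pattern
        for t, z in zip(tiles, zs):
            sites.extend(_interval_sites(t, 12, int(50 + 40 * np.sign(z)), 100))
        records = aggregate_modification(sites, tiles, min_cpg=10)
        return records

    def test_all_positive_tiles_fraction_one(self):
        records = self._records([1, 1, -1, 1])
        pos_tiles = [r.interval for r in records if r.z > 0]
        peaks = [
            NarrowPeak(GenomicInterval("chr1", t.start + 100, t.start + 300), 100,
                       fold_enrichment=2.0)
            for t in pos_tiles
        ]
        summary = peak_tile_concordance(peaks, records)
        assert summary.fraction_z_positive == 1.0

    def test_enriched_placement_recovers_high_fraction(self, rng):
        zs = list(rng.choice([-1, 1], size=200))
        records = self._records(zs)
        peaks = simulate_peaks_for_scores(
            [(r.interval, r.z) for r in records], n_peaks=300,
            enriched_fraction=0.9, seed=40,
        )
        summary = peak_tile_concordance(peaks, records)
        assert summary.fraction_z_positive > 0.8
        assert summary.n_assigned == 300

    def test_uniform_placement_matches_positive_tile_rate(self, rng):
        zs = list(rng.choice([-1, 1], size=400))
        records = self._records(zs)
        p_pos = sum(r.z > 0 for r in records) / len(records)
        peaks = simulate_peaks_for_scores(
            [(r.interval, r.z) for r in records], n_peaks=1_000,
            enriched_fraction=0.0, seed=41,
        )
        summary = peak_tile_concordance(peaks, records)
        se = math.sqrt(p_pos * (1 - p_pos) / 1_000)
        assert abs(summary.fraction_z_positive - p_pos) < 3 * se

    def test_zero_assigned_errors(self):
        records = self._records([1, -1, 1])
        far = [NarrowPeak(GenomicInterval("chr9", 0, 100), 50)]
        with pytest.raises(ValueError):
            peak_tile_concordance(far, records)


def _exact_binomial_tail(k, n, p):
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


class TestComposition:
    def test_hand_computed_tail(self):
        res = composition_test(["exon"] * 9 + ["intron"],
                               ["exon", "intron"] * 50)
        # p = 0.5, n = 10, k = 9 -> P(X >= 9) = 11/1024
        assert res["exon"].pvalue == pytest.approx(11 / 1024)

    def test_null_composition_not_significant(self):
        res = composition_test(["exon"] * 5 + ["intron"] * 5,
                               ["exon", "intron"] * 10)
        assert res["exon"].pvalue > 0.05

    def test_extreme_enrichment(self):
        res = composition_test(["promoter"] * 5,
                               ["promoter"] + ["intergenic"] * 9)
        assert res["promoter"].pvalue == pytest.approx(1e-5)

    def test_matches_exact_enumeration_for_small_n(self):
        for n, k, p_num in product((5, 12, 20), (0, 3, 5), (1, 5)):
            k = min(k, n)
            bg = ["a"] * p_num + ["b"] * (10 - p_num)
            peaks = ["a"] * k + ["b"] * (n - k)
            res = composition_test(peaks, bg)
            if "a" in res:
                assert res["a"].pvalue == pytest.approx(
                    _exact_binomial_tail(k, n, p_num / 10)
                )

    def test_class_absent_from_background_skipped(self):
        res = composition_test(["exotic", "exon"], ["exon"] * 10)
        assert "exotic" not in res and "exon" in res


class TestPrimaryFeature:
    def test_largest_cover_wins(self):
        tiles = [GenomicInterval("chr1", 0, 500)]
        feats = [
            GenomicInterval("chr1", 0, 200, feature_class="exon"),
            GenomicInterval("chr1", 200, 500, feature_class="intron"),
        ]
        assert primary_feature_of_tiles(tiles, feats)[("chr1", 0, 500)] == "intron"

    def test_tie_broken_by_priority(self):
        tiles = [GenomicInterval("chr1", 0, 400)]
        feats = [
            GenomicInterval("chr1", 0, 200, feature_class="intron"),
            GenomicInterval("chr1", 200, 400, feature_class="promoter"),
        ]
        assert primary_feature_of_tiles(tiles, feats)[("chr1", 0, 400)] == "promoter"


class TestCrossMethod:
    def _records(self, props):
        tiles = tile_genome({"chr1": 500 * len(props)}, width_bp=500)
        sites = []
        for t, p in zip(tiles, props):
            sites.extend(_interval_sites(t, 12, int(round(p * 100)), 100))
        return aggregate_modification(sites, tiles, min_cpg=10)

    def test_identical_records_rho_one(self):
        a = self._records([0.1, 0.2, 0.3, 0.4])
        assert cross_method_correlation(a, a).statistic == pytest.approx(1.0)

    def test_rank_reversed_rho_minus_one(self):
        a = self._records([0.1, 0.2, 0.3, 0.4])
        b = self._records([0.4, 0.3, 0.2, 0.1])
        assert cross_method_correlation(a, b).statistic == pytest.approx(-1.0)

    def test_noisy_observations_of_latent_field(self, rng):
        # two binomial observations of one latent enrichment field: the
        # Monte-Carlo band below was computed from the same generative model
        latent = rng.uniform(0.05, 0.6, size=300)
        tiles = tile_genome({"chr1": 500 * 300}, width_bp=500)

        def observe(seed):
            r = np.random.default_rng(seed)
            sites = []
            for t, p in zip(tiles, latent):
                k = int(r.binomial(100, p))
                sites.extend(_interval_sites(t, 12, 0, 100))
                # overwrite modified counts to k at each site
                for s in sites[-12:]:
                    s.n_5hmC = k
                    s.n_C = 100 - k
            return aggregate_modification(sites, tiles, min_cpg=10)

        res = cross_method_correlation(observe(1), observe(2))
        assert 0.9 < res.statistic <= 1.0
        assert res.pvalue < 1e-10

    def test_too_few_matched_errors(self):
        a = self._records([0.1, 0.2])
        with pytest.raises(ValueError):
            cross_method_correlation(a, a[:1])
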