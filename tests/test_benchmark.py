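"""Accuracy summaries, FPR stratifications, pileups, and deviation metrics."""

import math

import numpy as np
import pytest

from cpgdyad import (
    ConfusionParams,
    DepthModel,
    GenomicInterval,
    ReadCall,
    SiteCounts,
    confusion_summary,
    inter_assay,
    intra_assay,
    metrics_from_rates,
    percent_modification,
    pileup_from_reads,
    simulate_standards,
)
from cpgdyad.benchmark import (
    classification_error_5hmc,
    depth_gc_correlation,
    fpr_by_context,
    fpr_vs_gc,
)


def _calls(states, chrom="chr1", start=0, step=2, strand="+"):
    return [
        ReadCall(f"r{i}", chrom, start + step * i, strand, s)
        for i, s in enumerate(states)
    ]


class TestConfusionSummary:
    def test_published_rates_reproduce_published_metrics(self):
        precision, recall, f1 = metrics_from_rates(tpr=0.97, fpr=0.0056)
        assert round(precision, 2) == 0.99
        assert round(recall, 2) == 0.97
        assert round(f1, 2) == 0.98

    def test_all_correct(self):
        s = confusion_summary(_calls(["C"] * 10), _calls(["5mC"] * 10))
        assert (s.tpr, s.fpr) == (1.0, 0.0)
        assert s.precision == s.recall == s.f1 == 1.0

    def test_counting_matches_brute_force(self):
        # 10 true-C calls, 1 called 5mC; 10 true-5mC calls, 9 called 5mC
        neg = _calls(["C"] * 9 + ["5mC"])
        pos = _calls(["5mC"] * 9 + ["C"])
        s = confusion_summary(neg, pos)
        assert s.fpr == pytest.approx(0.1)
        assert s.tpr == pytest.approx(0.9)
        assert s.precision == pytest.approx(0.9 / (0.9 + 0.1))

    def test_fnr_identity_and_f1_harmonic_mean(self):
        s = confusion_summary(_calls(["C"] * 50 + ["5mC"] * 3),
                              _calls(["5mC"] * 40 + ["C"] * 5))
        assert s.fnr == pytest.approx(1.0 - s.tpr)
        hm = 2 * s.precision * s.recall / (s.precision + s.recall)
        assert s.f1 == pytest.approx(hm)

    def test_count_based_variant_differs_with_unequal_sizes(self):
        neg = _calls(["C"] * 99 + ["5mC"])            # 100 negative calls
        pos = _calls(["5mC"] * 9 + ["C"], start=1000)  # 10 positive calls
        rate = confusion_summary(neg, pos, from_rates=True)
        count = confusion_summary(neg, pos, from_rates=False)
        assert count.precision == pytest.approx(9 / 10)
        assert rate.precision != pytest.approx(count.precision)

    def test_duplex_calls_count_both_strands(self):
        neg = [ReadCall("r0", "chr1", 0, "+", "C", is_duplex=True,
                        partner_state="5mC")]
        s = confusion_summary(neg, _calls(["5mC"] * 4))
        assert s.fpr == pytest.approx(0.5)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            confusion_summary([], _calls(["5mC"]))

    def test_fpr_5mc_only_excludes_5hmc_misclassification(self):
        neg = _calls(["C"] * 96 + ["5mC", "5mC", "5hmC", "5hmC"])
        s = confusion_summary(neg, _calls(["5mC"] * 10))
        assert s.fpr == pytest.approx(0.04)
        assert s.fpr_5mc_only == pytest.approx(0.02)

    def test_5hmc_classification_error(self):
        pos = _calls(["5mC"] * 98 + ["5hmC"] * 2)
        assert classification_error_5hmc(pos) == pytest.approx(0.02)


class TestPercentModification:
    @pytest.mark.parametrize(
        "counts, expected",
        [((2, 1, 1), (25.0, 25.0)), ((10, 0, 0), (0.0, 0.0)), ((0, 0, 5), (0.0, 100.0))],
    )
    def test_formula(self, counts, expected):
        assert percent_modification(*counts) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            percent_modification(0, 0, 0)


class TestFprVsGc:
    def _windows(self, n=20, width=100):
        # window i covers [i*width, (i+1)*width) with GC at the bin midpoint
        return [
            (GenomicInterval("chr1", i * width, (i + 1) * width), (i + 0.5) / n)
            for i in range(n)
        ]

    def test_linear_fpr_gives_r_one(self):
        windows = self._windows()
        calls = []
        k = 0
        for i in range(20):
            # FPR rises linearly with the bin index: i modified per 100 calls
            for j in range(100):
                state = "5mC" if j < i else "C"
                calls.append(ReadCall(f"r{k}", "chr1", i * 100 + j, "+", state))
                k += 1
        rows, res = fpr_vs_gc(calls, windows)
        assert len(rows) == 20
        assert res.statistic == pytest.approx(1.0)

    def test_single_bin_flagged(self):
        windows = [(GenomicInterval("chr1", 0, 100), 0.41)]
        calls = _calls(["C"] * 10, step=5)
        _, res = fpr_vs_gc(calls, windows)
        assert math.isnan(res.statistic) and "fewer than 3" in res.note

    def test_simulated_gc_effect_detected(self):
        # confusion FPR scaled up with GC -> positive correlation, p < 0.05
        windows = self._windows()
        confusion = ConfusionParams(
            gc_modifier=lambda gc: 0.2 + 3.0 * gc,
        )
        rng = np.random.default_rng(30)
        calls = []
        for k in range(100_000):
            w = int(rng.integers(20))
            pos = w * 100 + int(rng.integers(100))
            probs = confusion.row("C", windows[w][1])
            state = ("C", "5mC", "5hmC")[rng.choice(3, p=probs)]
            calls.append(ReadCall(f"r{k}", "chr1", pos, "+", state))
        _, res = fpr_vs_gc(calls, windows)
        assert res.statistic > 0
        assert res.pvalue < 0.05


class TestFprByContext:
    def test_single_class_equals_genomic_mean(self):
        calls = _calls(["C"] * 9 + ["5mC"])
        ctx = {"everything": [GenomicInterval("chr1", 0, 10_000)]}
        table = fpr_by_context(calls, ctx)
        assert table["everything"]["fpr"] == table["genomic_mean"]["fpr"] == 0.1

    def test_clean_class_fpr_zero(self):
        calls = _calls(["C"] * 5) + _calls(["5mC"] * 5, start=1_000)
        ctx = {"clean": [GenomicInterval("chr1", 0, 100)]}
        assert fpr_by_context(calls, ctx)["clean"]["fpr"] == 0.0

    def test_doubled_fpr_in_repeats_recovered(self):
        # simple-repeat region has 2x the FPR of the rest; ratio within 3 SE
        rng = np.random.default_rng(31)
        base, boost = 0.01, 0.02
        calls = []
        for k in range(100_000):
            in_rep = k % 2 == 0
            pos = k if in_rep else 200_000 + k
            p = boost if in_rep else base
            state = "5mC" if rng.random() < p else "C"
            calls.append(ReadCall(f"r{k}", "chr1", pos, "+", state))
        ctx = {"simple_repeat": [GenomicInterval("chr1", 0, 150_000)]}
        table = fpr_by_context(calls, ctx)
        rep = table["simple_repeat"]
        n = rep["n_calls"]
        ratio = rep["fpr"] / base
        se_ratio = math.sqrt(boost * (1 - boost) / n) / base
        assert abs(ratio - 2.0) < 3 * se_ratio


class TestPileupFromReads:
    def test_depth_filter(self):
        calls = [ReadCall(f"r{i}", "chr1", 100, "+", "5mC") for i in range(4)]
        assert pileup_from_reads(calls, min_depth=5) == []

    def test_masked_site_dropped(self):
        calls = [ReadCall(f"r{i}", "chr1", 100, "+", "5mC") for i in range(100)]
        mask = [GenomicInterval("chr1", 50, 150)]
        assert pileup_from_reads(calls, min_depth=5, mask=mask) == []

    def test_percentages(self):
        calls = [ReadCall(f"r{i}", "chr1", 100, "+", "5mC") for i in range(3)]
        calls += [ReadCall(f"q{i}", "chr1", 100, "+", "C") for i in range(2)]
        (site,) = pileup_from_reads(calls, min_depth=5)
        assert site.pct_5mC == 60.0

    def test_duplex_contributes_both_strand_records(self):
        calls = [
            ReadCall(f"r{i}", "chr1", 100, "+", "5mC", is_duplex=True,
                     partner_state="C")
            for i in range(5)
        ]
        sites = pileup_from_reads(calls, min_depth=5)
        by_key = {s.key: s for s in sites}
        assert by_key[("chr1", 100, "+")].n_5mC == 5
        assert by_key[("chr1", 101, "-")].n_C == 5


def _binomial_replicates(rng, n_sites, depth, p):
    reps = []
    for _ in range(2):
        n_mod = rng.binomial(depth, p, size=n_sites)
        reps.append(
            [
                SiteCounts("chr1", 2 * i, "+", int(depth - m), int(m), 0)
                for i, m in enumerate(n_mod)
            ]
        )
    return reps


class TestDeviation:
    def test_identical_replicates_rmsd_zero(self):
        rep = [SiteCounts("chr1", 2 * i, "+", 5, 5, 0) for i in range(20)]
        for summary in intra_assay([rep, rep], depth_thresholds=[5, 10]):
            assert summary.rmsd == 0.0

    def test_hand_arithmetic_rmsd(self):
        a = [SiteCounts("chr1", 0, "+", 5, 5, 0), SiteCounts("chr1", 2, "+", 10, 0, 0)]
        b = [SiteCounts("chr1", 0, "+", 4, 6, 0), SiteCounts("chr1", 2, "+", 8, 2, 0)]
        # pct diffs: |50-60| = 10 and |0-20| = 20 -> RMSD = sqrt((100+400)/2)
        (summary,) = intra_assay([a, b], depth_thresholds=[5])
        assert summary.rmsd == pytest.approx(math.sqrt(250), abs=1e-9)

    def test_binomial_closed_form(self, rng):
        # RMSD of two binomial resamples of p at depth d: 100*sqrt(2p(1-p)/d)
        p, d, n = 0.5, 10, 100_000
        reps = _binomial_replicates(rng, n, d, p)
        (summary,) = intra_assay(reps, depth_thresholds=[d])
        expected = 100 * math.sqrt(2 * p * (1 - p) / d)
        assert summary.rmsd == pytest.approx(expected, rel=0.02)

    def test_inter_assay_hand_mad_rmsd(self):
        a = [SiteCounts("chr1", 2 * i, "+", 10, 0, 0) for i in range(3)]
        b = [
            SiteCounts("chr1", 0, "+", 10, 0, 0),
            SiteCounts("chr1", 2, "+", 9, 1, 0),
            SiteCounts("chr1", 4, "+", 0, 10, 0),
        ]
        # diffs (0, 10, 100): MAD = 10, RMSD = sqrt(10100/3)
        (summary,) = inter_assay([a], [b], depth_thresholds=[5])
        assert summary.mad == pytest.approx(10.0)
        assert summary.rmsd == pytest.approx(math.sqrt(10_100 / 3), abs=1e-9)

    def test_identical_methods_zero(self):
        rep = [SiteCounts("chr1", 2 * i, "+", 3, 7, 0) for i in range(10)]
        (summary,) = inter_assay([rep], [rep], depth_thresholds=[5])
        assert summary.rmsd == 0.0 and summary.mad == 0.0

    def test_n_sites_non_increasing_in_threshold(self, rng):
        reps = []
        for _ in range(2):
            depths = rng.integers(3, 30, size=500)
            reps.append(
                [
                    SiteCounts("chr1", 2 * i, "+", int(d // 2), int(d - d // 2), 0)
                    for i, d in enumerate(depths)
                ]
            )
        summaries = intra_assay(reps, depth_thresholds=[5, 10, 15, 20])
        ns = [s.n_sites_compared for s in summaries]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_no_matched_sites_flagged(self):
        a = [SiteCounts("chr1", 0, "+", 5, 0, 0)]
        b = [SiteCounts("chr2", 0, "+", 5, 0, 0)]
        (summary,) = intra_assay([a, b], depth_thresholds=[5])
        assert summary.n_sites_compared == 0 and not summary.defined


class TestDepthGc:
    def _pileup_with_depths(self, depths, width=100):
        sites = []
        for w, d in enumerate(depths):
            sites.append(SiteCounts("chr1", w * width + 10, "+", int(d), 0, 0))
        return sites

    def test_strictly_decreasing_depth_gives_rho_minus_one(self):
        windows = [
            (GenomicInterval("chr1", i * 100, (i + 1) * 100), 0.3 + 0.02 * i)
            for i in range(10)
        ]
        pileup = self._pileup_with_depths([100 - 5 * i for i in range(10)])
        res = depth_gc_correlation(pileup, windows)
        assert res.statistic == pytest.approx(-1.0)

    def test_simulated_negative_gc_coefficient_detected(self):
        from cpgdyad import simulate_read_calls, simulate_truth

        n_windows = 1_000
        windows = []
        gc_by_window = {}
        rng = np.random.default_rng(32)
        for i in range(n_windows):
            gc = float(rng.uniform(0.3, 0.7))
            windows.append((GenomicInterval("chr1", i * 100, (i + 1) * 100), gc))
            gc_by_window[i] = gc
        sites = [("chr1", i * 100 + 10) for i in range(n_windows)]
        truth = simulate_truth(sites, mode="dyad_table", seed=33)
        calls = simulate_read_calls(
            truth, DepthModel(mean_depth=10, gc_coefficient=-3.0, duplex_rate=0),
            seed=34, gc_of_site=lambda c, p: gc_by_window[p // 100],
        )
        pileup = pileup_from_reads(calls, min_depth=1)
        res = depth_gc_correlation(pileup, windows)
        assert res.statistic < 0
        assert res.pvalue < 0.05

    def test_constant_depth_flagged(self):
        windows = [
            (GenomicInterval("chr1", i * 100, (i + 1) * 100), 0.3 + 0.05 * i)
            for i in range(5)
        ]
        pileup = self._pileup_with_depths([7] * 5)
        res = depth_gc_correlation(pileup, windows)
        assert math.isnan(res.statistic) and "constant" in res.note


class TestStandardsEndToEnd:
    def test_default_simulator_reproduces_published_accuracy(self):
        neg, pos = simulate_standards(10_000, 5, seed=35)
        s = confusion_summary(neg, pos)
        r = s.rounded()
        assert r["precision"] == 0.99
        assert r["recall"] == 0.97
        assert r["f1"] == 0.98
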