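import math

import numpy as np
import pandas as pd
import pytest

import poolfreq as pf
from poolfreq.io import FIRMatrix, GenotypeCallMatrix
from poolfreq.quality import (ClusterStats, compute_cluster_stats,
                              filter_snps, weighted_deviation)
from poolfreq.simulate import SignalModel, simulate_inbred_panel


def _panel(fir_rows, call_rows, snps, samples):
    return (FIRMatrix(pd.DataFrame(fir_rows, index=snps, columns=samples)),
            GenotypeCallMatrix(pd.DataFrame(call_rows, index=snps,
                                            columns=samples)))


class TestClusterStats:
    def test_constant_cluster(self):
        fir, calls = _panel([[0.1, 0.1, 0.1]], [["AA", "AA", "AA"]],
                            ["s1"], ["a", "b", "c"])
        (cs,) = compute_cluster_stats(fir, calls)
        assert cs.mu_aa == pytest.approx(0.1)
        assert cs.sd_aa == pytest.approx(0.0, abs=1e-12)
        assert cs.n_aa == 3
        assert cs.n_bb == 0

    def test_sample_sd_convention(self):
        # sd uses the n-1 denominator: {0.08, 0.10, 0.12} -> sd = 0.02
        fir, calls = _panel([[0.08, 0.10, 0.12]], [["AA", "AA", "AA"]],
                            ["s1"], ["a", "b", "c"])
        (cs,) = compute_cluster_stats(fir, calls)
        assert cs.mu_aa == pytest.approx(0.10)
        assert cs.sd_aa == pytest.approx(0.02)

    def test_het_and_missing_excluded(self):
        fir, calls = _panel([[0.1, 0.5, 0.9, np.nan]],
                            [["AA", "AB", "BB", "BB"]],
                            ["s1"], ["a", "b", "c", "d"])
        (cs,) = compute_cluster_stats(fir, calls)
        assert cs.n_aa == 1 and cs.n_bb == 1
        assert math.isnan(cs.sd_aa)  # single member: sd undefined

    def test_empty_intersection_errors(self):
        fir, _ = _panel([[0.1]], [["AA"]], ["s1"], ["a"])
        _, calls = _panel([[0.1]], [["AA"]], ["s2"], ["b"])
        with pytest.raises(ValueError):
            compute_cluster_stats(fir, calls)


class TestWeightedDeviation:
    def test_pooled_denominator(self):
        cs = ClusterStats("s", 0.10, 0.02, 50, 0.90, 0.03, 50)
        wd = weighted_deviation(cs).wd
        expected = 0.8 / math.sqrt((50 * 0.0004 + 50 * 0.0009) / 100)
        assert wd == pytest.approx(expected)
        assert wd == pytest.approx(31.38, abs=0.01)

    def test_monomorphic_bb_substitution(self):
        # no AA lines: assume mu_AA = 0, sd_AA = 0
        cs = ClusterStats("s", math.nan, math.nan, 0, 0.95, 0.01, 100)
        rec = weighted_deviation(cs)
        assert rec.wd == pytest.approx(95.0)
        assert rec.monomorphic_side == "BB_only"

    def test_monomorphic_aa_substitution(self):
        # no BB lines: assume mu_BB = 1, sd_BB = 0
        cs = ClusterStats("s", 0.05, 0.01, 100, math.nan, math.nan, 0)
        rec = weighted_deviation(cs)
        assert rec.wd == pytest.approx(0.95 / 0.01)
        assert rec.monomorphic_side == "AA_only"

    def test_zero_variance_is_infinite(self):
        cs = ClusterStats("s", 0.1, 0.0, 10, 0.9, 0.0, 10)
        assert weighted_deviation(cs).wd == math.inf

    def test_undefined_when_no_usable_cluster(self):
        assert math.isnan(weighted_deviation(
            ClusterStats("s", math.nan, math.nan, 0, math.nan, math.nan, 0)).wd)
        # both clusters single-member
        assert math.isnan(weighted_deviation(
            ClusterStats("s", 0.1, math.nan, 1, 0.9, math.nan, 1)).wd)

    @pytest.mark.parametrize("scale", [0.5, 2.0])
    def test_scale_and_shift_properties(self, scale):
        base = ClusterStats("s", 0.2, 0.02, 40, 0.8, 0.03, 60)
        wd0 = weighted_deviation(base).wd
        scaled = ClusterStats("s", 0.2, 0.02 * scale, 40, 0.8, 0.03 * scale, 60)
        assert weighted_deviation(scaled).wd == pytest.approx(wd0 / scale)
        shifted = ClusterStats("s", 0.3, 0.02, 40, 0.9, 0.03, 60)
        assert weighted_deviation(shifted).wd == pytest.approx(wd0)

    def test_allele_relabel_symmetry(self):
        # swapping A<->B with FIR -> 1-FIR leaves wd unchanged
        cs = ClusterStats("s", 0.1, 0.02, 30, 0.85, 0.04, 70)
        sw = ClusterStats("s", 1 - 0.85, 0.04, 70, 1 - 0.1, 0.02, 30)
        assert weighted_deviation(sw).wd == pytest.approx(
            weighted_deviation(cs).wd)


class TestWdProperties:
    from hypothesis import given, settings, strategies as st

    @given(mu_a=st.floats(0.0, 0.4), gap=st.floats(0.05, 0.6),
           sd_a=st.floats(0.001, 0.1), sd_b=st.floats(0.001, 0.1),
           n_a=st.integers(2, 300), n_b=st.integers(2, 300))
    @settings(max_examples=60, derandomize=True)
    def test_relabel_and_scale_invariances(self, mu_a, gap, sd_a, sd_b,
                                           n_a, n_b):
        """wd is symmetric under allele relabeling (FIR -> 1-FIR) and
        scales inversely with a common rescaling of both cluster sds."""
        mu_b = mu_a + gap
        cs = ClusterStats("s", mu_a, sd_a, n_a, mu_b, sd_b, n_b)
        wd = weighted_deviation(cs).wd
        assert wd >= 0
        flipped = ClusterStats("s", 1 - mu_b, sd_b, n_b, 1 - mu_a, sd_a, n_a)
        assert weighted_deviation(flipped).wd == pytest.approx(wd, rel=1e-9)
        halved = ClusterStats("s", mu_a, sd_a / 2, n_a, mu_b, sd_b / 2, n_b)
        assert weighted_deviation(halved).wd == pytest.approx(2 * wd,
                                                              rel=1e-9)


class TestFilter:
    def test_threshold_is_strict(self):
        wds = [pf.WdRecord("lo", 49.9, "none"), pf.WdRecord("hi", 50.1, "none"),
               pf.WdRecord("at", 50.0, "none"),
               pf.WdRecord("inf", math.inf, "none"),
               pf.WdRecord("nan", math.nan, "none")]
        kept = filter_snps(wds, 50.0)
        assert kept == {"hi", "inf"}

    def test_het_parent_snps_removed(self):
        wds = [pf.WdRecord("good", 80.0, "none")]
        assert filter_snps(wds, 50.0, {"good"}) == set()

    def test_filter_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        wds = [pf.WdRecord(f"s{i}", w, "none")
               for i, w in enumerate(rng.uniform(0, 120, 200))]
        previous = None
        for thr in (10, 30, 50, 80):
            kept = filter_snps(wds, thr)
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_constructed_panel_splits_at_threshold(self):
        # 60 SNPs with tight clusters (wd >> 50), 40 with overlapping ones
        rng = np.random.default_rng(9)
        good = SignalModel(sd_aa=0.01, sd_bb=0.01, mean_jitter_sd=0.0)
        bad = SignalModel(mu_aa=0.35, mu_bb=0.65, sd_aa=0.15, sd_bb=0.15,
                          mean_jitter_sd=0.0)
        gc, gf = simulate_inbred_panel(60, 80, good, rng=rng)
        bc, bf = simulate_inbred_panel(40, 80, bad, rng=rng)
        bc.calls.index = bf.values.index = [f"BAD{i}" for i in range(40)]
        fir = FIRMatrix(pd.concat([gf.values, bf.values]))
        calls = GenotypeCallMatrix(pd.concat([gc.calls, bc.calls]))
        stats = compute_cluster_stats(fir, calls)
        kept = filter_snps([weighted_deviation(cs) for cs in stats], 50.0)
        assert kept == set(gf.values.index)
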