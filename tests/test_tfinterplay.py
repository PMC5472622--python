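"""Beta background fitting, one-sample K-S testing and interplay classification."""

import numpy as np
import pytest

from methintegrate.io import CpGRecord, GenomicInterval
from methintegrate.tfinterplay import (
    BackgroundModel,
    classify_interplay,
    extract_tf_methylation,
    fit_background,
    ks_test_against_background,
    promoter_windows,
)


class TestExtraction:
    WINDOWS = [GenomicInterval("chr1", 1000, 3000, "w1"),
               GenomicInterval("chr1", 5000, 7000, "w2")]

    def test_no_peaks_empty(self):
        meth = [CpGRecord("chr1", 1500, "+", 20, 10)]
        assert len(extract_tf_methylation(meth, [], self.WINDOWS)) == 0

    def test_extracts_window_cpgs(self):
        meth = [CpGRecord("chr1", 1500, "+", 20, 4), CpGRecord("chr1", 1600, "+", 20, 8)]
        peaks = [GenomicInterval("chr1", 1400, 1700, "pk")]
        vals = extract_tf_methylation(meth, peaks, self.WINDOWS)
        assert sorted(vals) == pytest.approx([0.2, 0.4])

    def test_one_bp_edge_overlap_includes_window(self):
        meth = [CpGRecord("chr1", 2900, "+", 20, 10)]
        peaks = [GenomicInterval("chr1", 2999, 3500, "pk")]  # 1 bp inside w1
        assert len(extract_tf_methylation(meth, peaks, self.WINDOWS)) == 1
        peaks_out = [GenomicInterval("chr1", 3000, 3500, "pk")]  # abuts, no overlap
        assert len(extract_tf_methylation(meth, peaks_out, self.WINDOWS)) == 0

    def test_coverage_filter(self):
        meth = [CpGRecord("chr1", 1500, "+", 5, 1)]
        peaks = [GenomicInterval("chr1", 1000, 3000, "pk")]
        assert len(extract_tf_methylation(meth, peaks, self.WINDOWS, min_coverage=10)) == 0


class TestBackgroundFit:
    def test_uniform_from_moments(self):
        a = np.sqrt(1.0 / 8.0)
        sample = np.array([0.5 - a, 0.5, 0.5 + a])  # mean .5, variance 1/12
        bg = fit_background(sample, min_n=3)
        assert bg.alpha == pytest.approx(1.0, abs=1e-9)
        assert bg.beta == pytest.approx(1.0, abs=1e-9)

    def test_worked_moments_inversion(self):
        sample = np.tile([0.1, 0.3], 100)  # mean .2, variance .01 -> k=15
        bg = fit_background(sample)
        assert bg.alpha == pytest.approx(3.0, abs=1e-9)
        assert bg.beta == pytest.approx(12.0, abs=1e-9)

    def test_estimator_consistency(self):
        rng = np.random.default_rng(8)
        bg = fit_background(rng.beta(2, 5, 50_000))
        assert abs(bg.alpha - 2) < 0.1 and abs(bg.beta - 5) < 0.1

    def test_overdispersed_sample_rejected(self):
        # all-extreme sample: v = m(1-m) exactly, outside Beta support
        sample = np.tile([0.0, 1.0], 100)
        with pytest.raises(ValueError, match="Beta support"):
            fit_background(sample, epsilon=0.0)

    def test_mle_refinement_close_to_truth(self):
        rng = np.random.default_rng(9)
        bg = fit_background(rng.beta(2, 5, 20_000), method="mle")
        assert abs(bg.alpha - 2) < 0.15 and abs(bg.beta - 5) < 0.3


class TestKS:
    def test_by_hand_example(self):
        d, _ = ks_test_against_background(np.array([0.1, 0.2, 0.3]),
                                          BackgroundModel(1.0, 1.0, 100))
        assert d == pytest.approx(0.7)

    def test_point_mass_at_median_d_half(self):
        bg = BackgroundModel(2.0, 2.0, 100)
        vals = np.full(10_000, 0.5)  # the Beta(2,2) median
        d, _ = ks_test_against_background(vals, bg)
        assert d == pytest.approx(0.5, abs=1e-3)

    def test_null_pvalues_uniform(self):
        bg = BackgroundModel(2.0, 2.0, 100)
        rng = np.random.default_rng(10)
        pvals = [ks_test_against_background(rng.beta(2, 2, 500), bg)[1]
                 for _ in range(200)]
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_test_against_background(np.array([]), BackgroundModel(1, 1, 10))

    def test_probability_integral_transform_invariance(self):
        # D computed on values vs Beta background equals D on the transformed
        # uniforms vs Uniform(0,1): F(x) is strictly increasing
        bg = BackgroundModel(2.0, 5.0, 100)
        rng = np.random.default_rng(11)
        x = rng.beta(1.5, 6.0, 400)
        d1, _ = ks_test_against_background(x, bg)
        u = bg.cdf(x)
        d2, _ = ks_test_against_background(u, BackgroundModel(1.0, 1.0, 100))
        assert d1 == pytest.approx(d2, abs=1e-9)


class TestClassify:
    def grid(self, rng, n_shifted=10, n_null=10, n=300):
        values = {}
        for i in range(n_shifted):
            values[("cell0", f"TF{i:03d}")] = rng.beta(1, 9, n)
        for i in range(n_null):
            values[("cell1", f"TF{i:03d}")] = rng.beta(2, 2, n)
        return values

    def test_power_and_size_on_mixed_grid(self):
        rng = np.random.default_rng(12)
        values = self.grid(rng)
        calls = classify_interplay(values, BackgroundModel(2.0, 2.0, 6000))
        shifted = [c for c in calls if c.cell == "cell0"]
        nulls = [c for c in calls if c.cell == "cell1"]
        assert sum(c.klass == "highly-differentiated" for c in shifted) >= 9
        assert sum(c.klass == "highly-differentiated" for c in nulls) <= 2

    def test_zero_cpg_combo_is_null(self):
        values = {("c", "t"): np.empty(0), ("c", "u"): np.random.default_rng(0).beta(2, 2, 200)}
        calls = classify_interplay(values, BackgroundModel(2, 2, 100))
        klass = {(c.cell, c.tf): c.klass for c in calls}
        assert klass[("c", "t")] == "null"

    def test_class_counts_conserved(self):
        rng = np.random.default_rng(13)
        values = self.grid(rng, n_shifted=4, n_null=4)
        values[("c2", "TF000")] = rng.beta(2, 2, 10)  # below min_sites -> null
        calls = classify_interplay(values, BackgroundModel(2, 2, 100))
        assert len(calls) == len(values)

    def test_bh_only_over_tested_combos(self):
        rng = np.random.default_rng(14)
        tested = {("c", f"t{i}"): rng.beta(2, 2, 200) for i in range(5)}
        with_nulls = {**tested, **{("d", f"t{i}"): np.empty(0) for i in range(50)}}
        a = classify_interplay(tested, BackgroundModel(2, 2, 100))
        b = classify_interplay(with_nulls, BackgroundModel(2, 2, 100))
        adj_a = {(c.cell, c.tf): c.adj_p for c in a}
        for c in b:
            if (c.cell, c.tf) in adj_a:
                assert c.adj_p == pytest.approx(adj_a[(c.cell, c.tf)])


def test_promoter_windows_width(plus_gene, minus_gene):
    w = promoter_windows([plus_gene, minus_gene], halfwidth=1000)
    assert [x.length for x in w] == [2000, 2000]
    assert w[0].start == 0 or w[0].end - w[0].start == 2000
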