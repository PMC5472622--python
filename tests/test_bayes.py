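"""Bayesian regression: design assembly, Gibbs sampler, Chib marginal
likelihood and model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from methintegrate.bayes import (
    PriorSpec,
    RegressionDataset,
    build_design,
    compare_models,
    gibbs_fit,
    log_marginal_likelihood,
    selection_probabilities,
    summarize_posterior,
)
from methintegrate.simulate import ExpressionTruth, GENOMIC_SEGMENTS, simulate_expression


def make_annotation(n_per_segment, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for seg, n in n_per_segment.items():
        for i in range(n):
            rows.append((f"{seg[:2]}{i:04d}", seg, float(rng.uniform(-60, 60))))
    return pd.DataFrame(rows, columns=["gene", "segment", "methy"])


def make_dge(annotation, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "id": annotation["gene"],
        "log2FoldChange": rng.normal(size=len(annotation)),
        "pval": rng.uniform(size=len(annotation)),
        "padj": rng.uniform(size=len(annotation)),
    })


class TestBuildDesign:
    def test_row_encoding(self):
        ann = pd.DataFrame([("g1", "promoter", 30.0)],
                           columns=["gene", "segment", "methy"])
        dge = pd.DataFrame({"id": ["g1"], "log2FoldChange": [0.5],
                            "pval": [0.01], "padj": [0.02]})
        ds = build_design(ann, dge, ["g1"], min_n=1, min_rows=1)
        assert ds.coefficient_names == ["Methy", "TSG", "GS[promoter]"]
        assert ds.X.tolist() == [[30.0, 1.0, 1.0]]

    def test_small_segment_dropped_and_recorded(self):
        ann = make_annotation({"promoter": 60, "3'UTR": 25})
        ds = build_design(ann, make_dge(ann), [], min_n=50)
        assert ds.dropped_segments == ["3'UTR"]
        assert ds.n == 60
        assert "GS[3'UTR]" not in ds.coefficient_names

    def test_single_segment_full_rank(self):
        ann = make_annotation({"CDS": 40})
        tsg = ann["gene"].iloc[:10].tolist()
        ds = build_design(ann, make_dge(ann), tsg, min_n=10)
        assert np.linalg.matrix_rank(ds.X) == ds.X.shape[1]

    def test_too_few_rows_refused(self):
        ann = make_annotation({"CDS": 5})
        with pytest.raises(ValueError, match="refusing"):
            build_design(ann, make_dge(ann), [], min_n=1)

    def test_hpro_column_and_zero_methy_exclusion(self):
        ann = make_annotation({"CDS": 30})
        ann.loc[0, "methy"] = 0.0
        ds = build_design(ann, make_dge(ann), [], min_n=1, include_hpro=True)
        assert ds.coefficient_names[-1] == "HPRO"
        assert ds.n == 29


class TestGibbs:
    def test_strong_prior_dominates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        ds = RegressionDataset(X=X, y=rng.normal(size=50),
                               coefficient_names=["a", "b"], gene_ids=list(range(50)))
        prior = PriorSpec(b0=3.0, B0=1e12, c0=2.0, d0=2.0)
        draws = gibbs_fit(ds, prior, iterations=2000, burn_in=500, seed=1)
        med = np.median(draws.beta_draws, axis=0)
        assert np.allclose(med, 3.0, atol=0.01)

    def test_same_seed_identical_draws(self, toy_regression):
        data, prior = toy_regression
        a = gibbs_fit(data, prior, iterations=1500, burn_in=200, seed=5)
        b = gibbs_fit(data, prior, iterations=1500, burn_in=200, seed=5)
        assert (a.beta_draws == b.beta_draws).all()
        assert (a.sigma2_draws == b.sigma2_draws).all()

    def test_rank_deficient_design_rejected(self):
        X = np.ones((20, 2))
        ds = RegressionDataset(X=X, y=np.zeros(20), coefficient_names=["a", "b"],
                               gene_ids=list(range(20)))
        with pytest.raises(ValueError, match="rank"):
            gibbs_fit(ds, PriorSpec(), iterations=100, burn_in=10)

    def test_known_variance_limit_matches_closed_form(self):
        # c0, d0 huge pins sigma^2 at d0/c0; beta posterior then has the
        # closed Gaussian form N((B0 + hX'X)^{-1}(B0 b0 + hX'y), .)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 2))
        beta_true = np.array([1.0, -0.5])
        sigma2 = 0.25
        y = X @ beta_true + rng.normal(0, np.sqrt(sigma2), 80)
        prior = PriorSpec(b0=0.0, B0=1e-2, c0=4e8, d0=1e8)  # sigma^2 ~ 0.25
        ds = RegressionDataset(X=X, y=y, coefficient_names=["a", "b"],
                               gene_ids=list(range(80)))
        draws = gibbs_fit(ds, prior, iterations=12_000, burn_in=2_000, seed=3)
        h = 1.0 / sigma2
        prec = np.eye(2) * 1e-2 + h * X.T @ X
        mean = np.linalg.solve(prec, h * X.T @ y)
        cov = np.linalg.inv(prec)
        for j in range(2):
            ks = stats.kstest(draws.beta_draws[:, j],
                              lambda v, jj=j: stats.norm.cdf(v, mean[jj],
                                                             np.sqrt(cov[jj, jj])))
            assert ks.statistic < 0.05


class TestChib:
    def quadrature_lml(self, data, prior):
        X, y = data.X[:, 0], data.y

        def integrand(b, h):
            lik = np.prod(stats.norm.pdf(y, X * b, np.sqrt(1.0 / h)))
            return (lik * stats.norm.pdf(b, prior.b0, np.sqrt(1.0 / prior.B0))
                    * stats.gamma.pdf(h, a=prior.c0 / 2, scale=2.0 / prior.d0))

        val, _ = integrate.dblquad(integrand, 1e-8, 200, lambda h: -5, lambda h: 5,
                                   epsabs=1e-12, epsrel=1e-9)
        return np.log(val)

    def test_toy_matches_quadrature(self, toy_regression):
        data, prior = toy_regression
        oracle = self.quadrature_lml(data, prior)
        draws = gibbs_fit(data, prior, iterations=6_000, burn_in=1_000, seed=0)
        est = log_marginal_likelihood(draws, data, prior)
        assert abs(est - oracle) < 0.05

    def test_deterministic_given_seed(self, toy_regression):
        data, prior = toy_regression
        ests = [log_marginal_likelihood(
            gibbs_fit(data, prior, iterations=3_000, burn_in=1_000, seed=9),
            data, prior) for _ in range(2)]
        assert ests[0] == ests[1]

    def test_too_few_draws_refused(self, toy_regression):
        data, prior = toy_regression
        draws = gibbs_fit(data, prior, iterations=1_200, burn_in=500, seed=0)
        with pytest.raises(ValueError, match="1000"):
            log_marginal_likelihood(draws, data, prior)


class TestComparison:
    def test_printed_worked_example(self):
        probs = selection_probabilities([-1335.051, -1339.274])
        assert probs[0] == pytest.approx(0.9855578, abs=1e-4)
        assert probs[1] == pytest.approx(0.0144422, abs=1e-4)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_lmls_give_half(self):
        assert selection_probabilities([-10.0, -10.0]) == pytest.approx([0.5, 0.5])

    def test_extreme_lmls_no_underflow(self):
        probs = selection_probabilities([-1e3, -2e3, -3e3])
        assert probs.sum() == pytest.approx(1.0)
        assert (probs >= 0).all()

    def test_differing_rows_rejected(self, toy_regression):
        data, prior = toy_regression
        other = RegressionDataset(X=data.X[:3], y=data.y[:3],
                                  coefficient_names=["b"], gene_ids=["a", "b", "c"])
        with pytest.raises(ValueError, match="identical row"):
            compare_models({"m1": data, "m2": other}, prior,
                           iterations=1200, burn_in=100)

    def test_base_model_preferred_without_hpro_effect(self):
        truth = ExpressionTruth(beta_methy=-0.02, beta_tsg=0.5,
                                beta_segment={s: 0.1 for s in GENOMIC_SEGMENTS},
                                sigma=0.5)
        dge, t = simulate_expression(truth, {s: 100 for s in GENOMIC_SEGMENTS}, seed=3)
        ann = t.gene_table[["gene", "segment", "methy"]]
        tsg = t.gene_table.loc[t.gene_table["tsg"], "gene"].tolist()
        base = build_design(ann, dge, tsg, min_n=50)
        variant = build_design(ann, dge, tsg, min_n=50, include_hpro=True)
        cmp = compare_models({"base": base, "base+HPRO": variant},
                             iterations=4_000, burn_in=1_000, seed=0)
        assert cmp.selected == "base"


class TestSummaries:
    def test_constant_draws(self):
        from methintegrate.bayes import PosteriorDraws

        draws = PosteriorDraws(beta_draws=np.full((100, 1), 2.5),
                               sigma2_draws=np.full(100, 0.1), burn_in=0,
                               coefficient_names=["c"], seed=0)
        out = summarize_posterior(draws)
        row = out[out["coefficient"] == "c"].iloc[0]
        assert row["median"] == row["ci_lo"] == row["ci_hi"] == 2.5

    def test_percentile_interpolation(self):
        from methintegrate.bayes import PosteriorDraws

        draws = PosteriorDraws(beta_draws=np.arange(1.0, 101.0)[:, None],
                               sigma2_draws=np.ones(100), burn_in=0,
                               coefficient_names=["c"], seed=0)
        row = summarize_posterior(draws).iloc[0]
        assert row["median"] == pytest.approx(50.5)
        assert row["ci_lo"] == pytest.approx(3.475)
        assert row["ci_hi"] == pytest.approx(97.525)

    def test_permutation_invariant(self):
        from methintegrate.bayes import PosteriorDraws

        rng = np.random.default_rng(4)
        b = rng.normal(size=(500, 2))
        perm = rng.permutation(500)
        a = summarize_posterior(PosteriorDraws(b, np.ones(500), 0, ["x", "y"], 0))
        c = summarize_posterior(PosteriorDraws(b[perm], np.ones(500)[perm], 0,
                                               ["x", "y"], 0))
        pd.testing.assert_frame_equal(a, c)
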