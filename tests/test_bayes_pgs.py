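import numpy as np
import pytest

from pgscontinuum import bayes_pgs, scoring, simdata
from pgscontinuum.bayes_pgs import LDMatrix, PosteriorSamples, PriorSpec, SummaryStats


class TestPriorSpec:
    def test_rejects_nonpositive_variances(self):
        with pytest.raises(ValueError):
            PriorSpec(sigma2_beta=0.0, sigma2_e=1.0)
        with pytest.raises(ValueError):
            PriorSpec(sigma2_beta=1.0, sigma2_e=-1.0)
        with pytest.raises(ValueError):
            PriorSpec(sigma2_beta=1.0, sigma2_e=1.0, sparsity=0.0)


class TestMarginalGwas:
    def test_null_phenotype_gives_null_effects(self, toy_panel):
        ss = bayes_pgs.marginal_gwas(toy_panel, np.zeros(toy_panel.n_individuals))
        np.testing.assert_array_equal(ss.beta_gwas, 0.0)

    def test_matches_per_snp_regression_loop(self, toy_fit):
        """Marginal effects equal univariate OLS per SNP to machine precision."""
        panel, X, y = toy_fit["panel"], toy_fit["X"], toy_fit["y"]
        ss = bayes_pgs.marginal_gwas(panel, toy_fit["ph"].y)
        n = panel.n_train
        for j in range(panel.n_snps):
            # marginal effect definition: x'y/N on standardized genotypes
            np.testing.assert_allclose(
                ss.beta_gwas[j], X[:, j] @ y / n, rtol=0, atol=1e-12
            )

    def test_self_regression_recovers_unity(self):
        """y equal to one standardized SNP gives a marginal effect of ~1 there."""
        model = simdata.single_ancestry_model(n_train=300, n_test=0, M=5, seed=31)
        panel = simdata.simulate_genotype_panel(model).drop_monomorphic()
        X = simdata.standardize_genotypes(panel, rows=panel.is_train)
        ss = bayes_pgs.marginal_gwas(panel, X[:, 0])
        assert abs(ss.beta_gwas[0] - X[:, 0] @ X[:, 0] / panel.n_train) < 1e-12

    def test_length_mismatch_raises(self, toy_panel):
        with pytest.raises(ValueError, match="length"):
            bayes_pgs.marginal_gwas(toy_panel, np.zeros(7))

    def test_covariate_residualization(self, toy_fit):
        """Adding a covariate equal to y zeroes all marginal effects."""
        panel, ph = toy_fit["panel"], toy_fit["ph"]
        cov = ph.y[panel.is_train][:, None]
        ss = bayes_pgs.marginal_gwas(panel, ph.y, covariates=cov)
        np.testing.assert_allclose(ss.beta_gwas, 0.0, atol=1e-10)


class TestLDMatrix:
    def test_matches_pairwise_correlation_oracle(self, toy_panel):
        ld = bayes_pgs.ld_from_panel(toy_panel)
        X = simdata.standardize_genotypes(toy_panel, rows=toy_panel.is_train)
        oracle = np.corrcoef(X, rowvar=False)
        np.testing.assert_allclose(ld.R, oracle, atol=1e-10)

    def test_duplicated_snp_column_unit_correlation(self):
        geno = np.random.default_rng(0).integers(0, 3, size=(50, 4)).astype(np.int8)
        geno[:, 3] = geno[:, 0]
        panel = simdata.GenotypePanel(
            genotypes=geno, snp_ids=list("abcd"),
            individual_ids=[str(i) for i in range(50)],
            is_train=np.ones(50, dtype=bool),
        )
        ld = bayes_pgs.ld_from_panel(panel)
        assert abs(ld.R[0, 3] - 1.0) < 1e-12

    def test_off_diagonals_shrink_with_n(self):
        """Independent SNPs: mean |r| scales like N^{-1/2}."""
        means = {}
        for n in (100, 400):
            model = simdata.single_ancestry_model(n_train=n, n_test=0, M=60, seed=5)
            panel = simdata.simulate_genotype_panel(model).drop_monomorphic()
            R = bayes_pgs.ld_from_panel(panel).R
            off = R[np.triu_indices_from(R, k=1)]
            means[n] = np.abs(off).mean()
        ratio = means[100] / means[400]
        assert 1.5 < ratio < 2.7  # sqrt(4) = 2 within Monte-Carlo slack

    def test_too_few_training_individuals(self):
        geno = np.array([[0, 1, 2]], dtype=np.int8)
        panel = simdata.GenotypePanel(
            genotypes=geno, snp_ids=list("abc"), individual_ids=["x"],
            is_train=np.array([True]),
        )
        with pytest.raises(ValueError, match="training"):
            bayes_pgs.ld_from_panel(panel)


class TestInfinitesimalPosterior:
    def test_matches_dense_solve(self, toy_fit):
        """mu_beta and x'Sigma_beta x equal the dense-matrix formulas to 1e-8."""
        panel, X, y, Xt = (
            toy_fit["panel"], toy_fit["X"], toy_fit["y"], toy_fit["Xt"],
        )
        prior = toy_fit["prior"]
        ridge = toy_fit["ridge"]
        a = prior.sigma2_e / prior.sigma2_beta
        A = a * np.eye(panel.n_snps) + X.T @ X
        mu_dense = np.linalg.solve(A, X.T @ y)
        Sig = prior.sigma2_e * np.linalg.inv(A)
        np.testing.assert_allclose(ridge.mu_beta, mu_dense, atol=1e-8)
        quad_dense = np.einsum("ij,jk,ik->i", Xt[:5], Sig, Xt[:5])
        np.testing.assert_allclose(
            ridge.liability_variance(Xt[:5]), quad_dense, atol=1e-8
        )

    def test_infinite_shrinkage_limit(self, toy_fit):
        prior = PriorSpec(sigma2_beta=1e-12, sigma2_e=1.0)
        ridge = bayes_pgs.fit_infinitesimal_posterior(
            toy_fit["panel"], toy_fit["ph"].y, prior
        )
        assert np.abs(ridge.mu_beta).max() < 1e-6

    def test_single_snp_scalar_shrinkage(self):
        """One SNP: mu = lambda/(lambda + sigma_e^2/sigma_b^2) * (x'y)/lambda."""
        model = simdata.single_ancestry_model(n_train=120, n_test=0, M=1, seed=41)
        panel = simdata.simulate_genotype_panel(model).drop_monomorphic()
        X = simdata.standardize_genotypes(panel, rows=panel.is_train)
        rng = np.random.default_rng(2)
        y = 0.3 * X[:, 0] + rng.normal(size=panel.n_train)
        prior = PriorSpec(sigma2_beta=0.1, sigma2_e=1.0)
        ridge = bayes_pgs.fit_infinitesimal_posterior(panel, y, prior)
        lam = float(X[:, 0] @ X[:, 0])
        expected = lam / (lam + prior.sigma2_e / prior.sigma2_beta) * (X[:, 0] @ y) / lam
        assert abs(ridge.mu_beta[0] - expected) < 1e-12

    def test_requires_infinitesimal_prior(self, toy_fit):
        prior = PriorSpec(sigma2_beta=0.1, sigma2_e=1.0, sparsity=0.5)
        with pytest.raises(ValueError, match="sparsity"):
            bayes_pgs.fit_infinitesimal_posterior(
                toy_fit["panel"], toy_fit["ph"].y, prior
            )


class TestGibbsSampler:
    def test_null_summary_stats_centred_posterior(self):
        """With beta_hat exactly 0 the posterior means sit at 0."""
        M = 30
        ld = LDMatrix(R=np.eye(M), snp_ids=[f"s{i}" for i in range(M)])
        ss = SummaryStats(
            snp_ids=ld.snp_ids, beta_gwas=np.zeros(M), n_gwas=np.full(M, 500.0)
        )
        samples = bayes_pgs.gibbs_spike_slab(ss, ld, seed=3)
        mean = samples.draws.mean(axis=0)
        mcse = samples.draws.std(axis=0) / np.sqrt(samples.B) + 1e-12
        assert np.all(np.abs(mean) <= 3.5 * mcse + 1e-9)

    def test_slab_only_matches_analytic_ridge(self, toy_fit):
        """Conjugate limit: sparsity fixed at 1 recovers the ridge posterior
        within Monte-Carlo error for linear functionals x'beta."""
        panel, ph = toy_fit["panel"], toy_fit["ph"]
        prior = toy_fit["prior"]
        ridge = toy_fit["ridge"]
        ss = bayes_pgs.marginal_gwas(panel, ph.y)
        ld = bayes_pgs.ld_from_panel(panel)
        samples = bayes_pgs.gibbs_spike_slab(
            ss, ld, seed=10, p_init=np.ones(4),
            h2_init=prior.sigma2_beta * panel.n_snps,
            update_p=False, update_h2=False,
            n_iter=2100, burn_in=100, thin=5,
        )
        Xt = toy_fit["Xt"][:5]
        lp = scoring.posterior_liability(Xt, samples)
        mu_an = ridge.predict(Xt)
        var_an = ridge.liability_variance(Xt)
        mcse = np.sqrt(lp.var_ghat / samples.B)
        assert np.all(np.abs(lp.ghat - mu_an) <= 3.0 * mcse)
        # posterior variance of the functional agrees within chi^2 noise
        assert np.all(np.abs(lp.var_ghat / var_an - 1.0) < 4.0 * np.sqrt(2.0 / samples.B))

    def test_recovers_heritability(self):
        """Parameter recovery at the non-European simulation scale:
        h2_true=0.8, p_causal=0.01, M=2,000, N=5,000."""
        model = simdata.single_ancestry_model(n_train=5_000, n_test=0, M=2_000, seed=51)
        panel = simdata.simulate_genotype_panel(model).drop_monomorphic()
        arch = simdata.simulate_architecture(panel, 0.8, 0.01, seed=52)
        (ph,) = simdata.simulate_phenotypes(panel, arch, 1, seed=53)
        ss = bayes_pgs.marginal_gwas(panel, ph.y)
        ld = bayes_pgs.ld_from_panel(panel)
        samples = bayes_pgs.chain_qc(bayes_pgs.gibbs_spike_slab(ss, ld, seed=54))
        assert 0.6 <= samples.h2_estimate <= 1.0

    def test_seed_reproducibility(self):
        M = 20
        rng = np.random.default_rng(6)
        ld = LDMatrix(R=np.eye(M), snp_ids=[f"s{i}" for i in range(M)])
        ss = SummaryStats(
            snp_ids=ld.snp_ids, beta_gwas=rng.normal(0, 0.05, M),
            n_gwas=np.full(M, 400.0),
        )
        a = bayes_pgs.gibbs_spike_slab(ss, ld, seed=7)
        b = bayes_pgs.gibbs_spike_slab(ss, ld, seed=7)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_mismatched_snp_sets_rejected(self):
        ld = LDMatrix(R=np.eye(2), snp_ids=["a", "b"])
        ss = SummaryStats(snp_ids=["a", "c"], beta_gwas=np.zeros(2),
                          n_gwas=np.full(2, 100.0))
        with pytest.raises(ValueError, match="SNP"):
            bayes_pgs.gibbs_spike_slab(ss, ld)


def _fake_samples(h2_per_chain, sparsity_per_chain, n_keep=10, M=4):
    n_chains = len(h2_per_chain)
    rng = np.random.default_rng(0)
    return PosteriorSamples(
        draws=rng.normal(size=(n_chains * n_keep, M)),
        chain_id=np.repeat(np.arange(n_chains), n_keep),
        h2_per_chain=np.asarray(h2_per_chain, dtype=float),
        sparsity_per_chain=np.asarray(sparsity_per_chain, dtype=float),
        h2_traces=np.tile(np.asarray(h2_per_chain)[:, None], (1, 20)),
        p_traces=np.tile(np.asarray(sparsity_per_chain)[:, None], (1, 20)),
        snp_ids=[f"s{i}" for i in range(M)],
    )


class TestChainQC:
    def test_identical_chains_all_retained(self):
        s = _fake_samples([0.3] * 10, [0.01] * 10, n_keep=100)
        q = bayes_pgs.chain_qc(s)
        assert q.B == 1000
        assert q.qc_report["removed_chains"] == []

    def test_low_heritability_chain_removed(self):
        h2 = [0.3] * 9 + [0.15]  # 0.5x the median of ten
        s = _fake_samples(h2, [0.01] * 10)
        q = bayes_pgs.chain_qc(s)
        assert q.qc_report["removed_chains"] == [9]
        assert q.B == 90

    def test_high_sparsity_chain_removed(self):
        p = [0.01] * 9 + [0.03]  # 3x the median
        s = _fake_samples([0.3] * 10, p)
        q = bayes_pgs.chain_qc(s)
        assert q.qc_report["removed_chains"] == [9]

    def test_low_sparsity_chain_removed(self):
        p = [0.01] * 9 + [0.004]  # 0.4x the median
        s = _fake_samples([0.3] * 10, p)
        q = bayes_pgs.chain_qc(s)
        assert q.qc_report["removed_chains"] == [9]

    def test_boundary_chains_retained(self):
        # exactly 0.7x median h2 and 2x / 0.5x median sparsity are kept
        s = _fake_samples([0.3] * 9 + [0.21], [0.01] * 8 + [0.02, 0.005])
        q = bayes_pgs.chain_qc(s)
        assert q.qc_report["removed_chains"] == []

    def test_all_chains_removed_raises(self):
        s = _fake_samples([0.3, 0.1], [0.01, 0.0001])
        # medians make both chains fail one filter each
        s.h2_per_chain = np.array([1.0, 0.1])
        s.sparsity_per_chain = np.array([0.0001, 0.1])
        with pytest.raises(RuntimeError, match="chains"):
            bayes_pgs.chain_qc(s)

    def test_draw_count_arithmetic(self):
        """600 iterations, 100 burn-in, thin 5 -> 100 draws per chain."""
        M = 10
        ld = LDMatrix(R=np.eye(M), snp_ids=[f"s{i}" for i in range(M)])
        ss = SummaryStats(snp_ids=ld.snp_ids, beta_gwas=np.zeros(M),
                          n_gwas=np.full(M, 200.0))
        samples = bayes_pgs.gibbs_spike_slab(ss, ld, seed=8)
        assert samples.B == 1000  # 10 chains x 100 draws
        q = bayes_pgs.chain_qc(samples)
        assert q.B % 100 == 0 and 100 <= q.B <= 1000
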