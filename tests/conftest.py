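import numpy as np
import pytest

from pgscontinuum import (
    ancestry,
    bayes_pgs,
    scoring,
    simdata,
)


@pytest.fixture(scope="session")
def toy_panel():
    """Small single-ancestry panel for exact/oracle checks."""
    model = simdata.single_ancestry_model(n_train=200, n_test=20, M=40, seed=17)
    return simdata.simulate_genotype_panel(model).drop_monomorphic()


@pytest.fixture(scope="session")
def toy_fit(toy_panel):
    """Ridge posterior + matching dense-oracle ingredients on the toy panel."""
    arch = simdata.simulate_architecture(toy_panel, 0.5, 1.0, seed=18)
    (ph,) = simdata.simulate_phenotypes(toy_panel, arch, 1, seed=19)
    prior = bayes_pgs.PriorSpec(sigma2_beta=0.5 / toy_panel.n_snps, sigma2_e=0.5)
    ridge = bayes_pgs.fit_infinitesimal_posterior(toy_panel, ph.y, prior)
    X = simdata.standardize_genotypes(toy_panel, rows=toy_panel.is_train)
    Xt = simdata.standardize_genotypes(toy_panel, rows=~toy_panel.is_train)
    y = ph.y[toy_panel.is_train]
    return dict(panel=toy_panel, ph=ph, prior=prior, ridge=ridge, X=X, Xt=Xt, y=y)


@pytest.fixture(scope="session")
def calibration_run():
    """Full-size calibration study shared by the acceptance tests:
    M=2,000 SNPs, 5,000 training and 200 test individuals of the training
    ancestry, h2=0.25, p_causal=0.01, 100 replicates with effects and noise
    redrawn, full refit per replicate."""
    from pgscontinuum.pipeline import calibration_study

    return calibration_study(n_replicates=100, seed=1)


@pytest.fixture(scope="session")
def gradient_run():
    """Gradient-scenario run shared by the continuum-decay tests: 500 test
    individuals along a 0->1 admixture gradient, accuracy and CI width
    averaged across 5 simulation replicates."""
    from pgscontinuum import evaluation
    from pgscontinuum.pipeline import stage_seed

    model = simdata.gradient_model(n_train=5_000, n_test=500, M=2_000, seed=21)
    panel = simdata.simulate_genotype_panel(model).drop_monomorphic()
    ld = bayes_pgs.ld_from_panel(panel)
    basis = ancestry.fit_pca(panel, J=20, snp_ids=ancestry.ld_prune(panel))
    xb = ancestry.standardize_for_basis(panel, basis, rows=~panel.is_train)
    scores = ancestry.project(xb, basis)
    gd = ancestry.genetic_distance(scores)
    X_test = simdata.standardize_genotypes(panel, rows=~panel.is_train)
    reps = simdata.simulate_replicates(panel, 0.25, 0.01, n_replicates=5, seed=22)
    r2s, widths, ghats, gs = [], [], [], []
    for r, (arch, ph) in enumerate(reps):
        ss = bayes_pgs.marginal_gwas(panel, ph.y)
        samples = bayes_pgs.chain_qc(
            bayes_pgs.gibbs_spike_slab(ss, ld, seed=stage_seed(22, f"gibbs-{r}"))
        )
        lp = scoring.posterior_liability(X_test, samples)
        acc = scoring.individual_accuracy(lp, samples.h2_estimate)
        r2s.append(acc.r2)
        widths.append(lp.ci_high - lp.ci_low)
        ghats.append(lp.ghat)
        gs.append(ph.g[~panel.is_train])
    return dict(
        panel=panel,
        basis=basis,
        xb=xb,
        scores=scores,
        gd=gd,
        r2_mean=np.mean(r2s, axis=0),
        width_mean=np.mean(widths, axis=0),
        r2_per_rep=np.array(r2s),
        ghat_per_rep=np.array(ghats),
        g_per_rep=np.array(gs),
    )
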