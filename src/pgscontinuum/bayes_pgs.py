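"""Bayesian polygenic-score inference.

Two routes to the posterior of standardized SNP effects:

* an exact infinitesimal (ridge) posterior obtained through the
  eigendecomposition of the training genotype matrix, and
* a summary-statistics spike-and-slab Gibbs sampler in the LDpred family,
  with automatic hyperparameters: the causal proportion p gets a conjugate
  Beta update from the inclusion counts, and the heritability h2 is
  recomputed each iteration from the current effect draw as beta' R beta.

The sampler runs multiple chains started at log-spaced initial sparsity,
then chains are quality-controlled against the cross-chain medians of their
h2 and sparsity estimates before burn-in removal and thinning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numba
import numpy as np

from .simdata import GenotypePanel, standardize_genotypes

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "SummaryStats",
    "LDMatrix",
    "RidgePosterior",
    "PosteriorSamples",
    "marginal_gwas",
    "ld_from_panel",
    "fit_infinitesimal_posterior",
    "gibbs_spike_slab",
    "chain_qc",
]

# Sampler schedule: 100 burn-in iterations, then 500 retained iterations
# thinned by 5 -> 100 stored draws per chain; 10 chains with initial
# sparsity log-spaced between 1e-4 and 1.
N_CHAINS = 10
N_ITER = 600
BURN_IN = 100
THIN = 5
P_INIT_RANGE = (1e-4, 1.0)
# Chain QC thresholds relative to the cross-chain medians.
QC_H2_MIN_FRAC = 0.7
QC_P_MIN_FRAC = 0.5
QC_P_MAX_FRAC = 2.0


@dataclass
class PriorSpec:
    """Gaussian(-mixture) prior on standardized effects."""

    sigma2_beta: float
    sigma2_e: float
    sparsity: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_beta <= 0 or self.sigma2_e <= 0:
            raise ValueError("prior variances must be positive")
        if not (0.0 < self.sparsity <= 1.0):
            raise ValueError("sparsity must lie in (0, 1]")


@dataclass
class SummaryStats:
    """Marginal standardized GWAS effects with per-SNP sample size."""

    snp_ids: list[str]
    beta_gwas: np.ndarray
    n_gwas: np.ndarray

    def __post_init__(self) -> None:
        self.beta_gwas = np.asarray(self.beta_gwas, dtype=float)
        self.n_gwas = np.broadcast_to(
            np.asarray(self.n_gwas, dtype=float), self.beta_gwas.shape
        ).copy()
        if not np.all(np.isfinite(self.beta_gwas)):
            raise ValueError("non-finite marginal effects")


@dataclass
class LDMatrix:
    """SNP correlation matrix of standardized training genotypes.

    ``diag_scale`` holds the empirical standard deviations s_j of the
    allele-frequency-standardized columns (close to but not exactly 1), so
    that the raw second-moment matrix X'X/N = diag(s) R diag(s) can be
    reconstructed exactly by the sampler.
    """

    R: np.ndarray
    snp_ids: list[str]
    diag_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")


def marginal_gwas(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> SummaryStats:
    """Per-SNP marginal OLS effects on standardized training genotypes.

    With columns standardized to unit variance in the training set, the
    marginal effect reduces to x_j' y / N (after residualizing the
    phenotype on covariates, if any).
    """
    phenotype = np.asarray(phenotype, dtype=float)
    n_train = panel.n_train
    if phenotype.shape[0] == panel.n_individuals:
        y = phenotype[panel.is_train]
    elif phenotype.shape[0] == n_train:
        y = phenotype.copy()
    else:
        raise ValueError("phenotype length does not match panel")
    if covariates is not None:
        C = np.column_stack([np.ones(n_train), np.asarray(covariates, dtype=float)])
        y = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    X = standardize_genotypes(panel, rows=panel.is_train)
    beta = X.T @ y / n_train
    return SummaryStats(
        snp_ids=list(panel.snp_ids),
        beta_gwas=beta,
        n_gwas=np.full(panel.n_snps, float(n_train)),
    )


def ld_from_panel(panel: GenotypePanel) -> LDMatrix:
    """In-sample LD of standardized training genotypes.

    Columns have exactly zero training mean, so rescaling X'X/N by its
    diagonal yields the exact pairwise Pearson correlation matrix.
    """
    if panel.n_train < 2:
        raise ValueError("need at least 2 training individuals for LD")
    X = standardize_genotypes(panel, rows=panel.is_train)
    Rn = X.T @ X / panel.n_train
    Rn = (Rn + Rn.T) / 2.0
    s = np.sqrt(np.diag(Rn))
    C = Rn / np.outer(s, s)
    np.fill_diagonal(C, 1.0)
    return LDMatrix(R=C, snp_ids=list(panel.snp_ids), diag_scale=s)


@dataclass
class RidgePosterior:
    """Exact posterior under the infinitesimal prior, in eigenbasis form.

    mu_beta = (sigma2_e/sigma2_beta I + X'X)^{-1} X'y; the posterior
    covariance Sigma_beta = sigma2_e (sigma2_e/sigma2_beta I + X'X)^{-1} is
    represented by the eigenpairs (lambda_j, v_j) of X'X plus the residual
    null-space mass, never materialized as an M x M matrix.
    """

    mu_beta: np.ndarray
    eigvals: np.ndarray  # descending, lambda_j of X'X
    eigvecs: np.ndarray  # M x r, columns v_j
    prior: PriorSpec

    def liability_variance(self, x: np.ndarray) -> np.ndarray:
        """x' Sigma_beta x for one or many standardized genotype rows."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        a = self.prior.sigma2_e / self.prior.sigma2_beta
        s = x @ self.eigvecs  # n x r
        xtx = np.einsum("ij,ij->i", x, x)
        rest = np.maximum(xtx - np.einsum("ij,ij->i", s, s), 0.0)
        quad = (s**2 / (a + self.eigvals)).sum(axis=1) + rest / a
        return self.prior.sigma2_e * quad

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(x, dtype=float)) @ self.mu_beta


def fit_infinitesimal_posterior(
    panel: GenotypePanel, phenotype: np.ndarray, prior: PriorSpec
) -> RidgePosterior:
    """Closed-form ridge posterior via SVD of the training genotype matrix."""
    if prior.sparsity != 1.0:
        raise ValueError("infinitesimal posterior requires sparsity = 1")
    phenotype = np.asarray(phenotype, dtype=float)
    y = (
        phenotype[panel.is_train]
        if phenotype.shape[0] == panel.n_individuals
        else phenotype
    )
    X = standardize_genotypes(panel, rows=panel.is_train)
    U, d, Vt = np.linalg.svd(X, full_matrices=False)
    a = prior.sigma2_e / prior.sigma2_beta
    mu = Vt.T @ ((d / (d**2 + a)) * (U.T @ y))
    return RidgePosterior(mu_beta=mu, eigvals=d**2, eigvecs=Vt.T, prior=prior)


# ---------------------------------------------------------------------------
# Spike-and-slab Gibbs sampler
# ---------------------------------------------------------------------------


@numba.njit(cache=True)
def _gibbs_chain(
    bhat, R, diag, n, p0, h20, n_iter, burn_in, thin, update_p, update_h2, seed
):  # pragma: no cover - exercised through gibbs_spike_slab
    M = bhat.shape[0]
    np.random.seed(seed)
    beta = np.zeros(M)
    r = np.zeros(M)  # running R @ beta (R includes its true diagonal)
    p = p0
    h2 = h20
    n_keep = (n_iter - burn_in) // thin
    draws = np.zeros((n_keep, M))
    h2_trace = np.empty(n_iter)
    p_trace = np.empty(n_iter)
    tau2 = np.empty(M)
    kept = 0
    for it in range(n_iter):
        sigma2 = h2 / (M * p)
        se2 = 1.0 - h2
        if se2 < 0.01:
            se2 = 0.01
        prec = n / se2
        for j in range(M):
            tau2[j] = 1.0 / (prec * diag[j] + 1.0 / sigma2)
        n_incl = 0
        for j in range(M):
            omega = bhat[j] - r[j] + diag[j] * beta[j]
            mu = tau2[j] * prec * omega
            if p >= 1.0:
                pj = 1.0
            else:
                log_odds = (
                    np.log(p / (1.0 - p))
                    + 0.5 * np.log(tau2[j] / sigma2)
                    + 0.5 * mu * mu / tau2[j]
                )
                if log_odds > 35.0:
                    pj = 1.0
                elif log_odds < -35.0:
                    pj = 0.0
                else:
                    pj = 1.0 / (1.0 + np.exp(-log_odds))
            new = 0.0
            if np.random.random() < pj:
                new = mu + np.sqrt(tau2[j]) * np.random.normal()
                n_incl += 1
            delta = new - beta[j]
            if delta != 0.0:
                beta[j] = new
                for k in range(M):
                    r[k] += R[j, k] * delta
        if update_p:
            p = np.random.beta(1.0 + n_incl, 1.0 + M - n_incl)
            if p < 1e-5:
                p = 1e-5
        if update_h2:
            h2 = 0.0
            for j in range(M):
                h2 += beta[j] * r[j]
            if h2 < 0.01:
                h2 = 0.01
            elif h2 > 1.0:
                h2 = 1.0
        h2_trace[it] = h2
        p_trace[it] = p
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            draws[kept] = beta
            kept += 1
    return draws, h2_trace, p_trace


@dataclass
class PosteriorSamples:
    """Thinned posterior effect draws with per-chain hyperparameter traces."""

    draws: np.ndarray  # B x M
    chain_id: np.ndarray  # B
    h2_per_chain: np.ndarray
    sparsity_per_chain: np.ndarray
    h2_traces: np.ndarray  # n_chains x n_iter
    p_traces: np.ndarray
    snp_ids: list[str]
    qc_report: dict | None = None

    @property
    def B(self) -> int:
        return self.draws.shape[0]

    @property
    def h2_estimate(self) -> float:
        """Median h2 estimate over (retained) chains."""
        return float(np.median(self.h2_per_chain))


def gibbs_spike_slab(
    sumstats: SummaryStats,
    ld: LDMatrix,
    n_gwas: float | None = None,
    n_chains: int = N_CHAINS,
    n_iter: int = N_ITER,
    burn_in: int = BURN_IN,
    thin: int = THIN,
    seed: int = 0,
    p_init: np.ndarray | None = None,
    h2_init: float | None = None,
    update_p: bool = True,
    update_h2: bool = True,
) -> PosteriorSamples:
    """Run the multi-chain spike-and-slab Gibbs sampler on summary statistics.

    Each single-site update residualizes the marginal effect against the
    current draw through the LD matrix, computes the posterior inclusion
    probability from the spike-and-slab conditional, and draws the effect
    from the slab conditional when included.  Setting ``update_p=False``
    with ``p_init`` all ones gives the slab-only (ridge) sampler used for
    the conjugate-limit cross-check.
    """
    if sumstats.snp_ids != ld.snp_ids:
        raise ValueError("summary statistics and LD matrix cover different SNPs")
    M = len(sumstats.snp_ids)
    bhat = np.ascontiguousarray(sumstats.beta_gwas)
    if ld.diag_scale is not None:
        # Reconstruct the raw second-moment matrix X'X/N so the single-site
        # conditionals match the individual-data posterior exactly.
        s = np.asarray(ld.diag_scale, dtype=float)
        R = np.ascontiguousarray(ld.R * np.outer(s, s))
    else:
        R = np.ascontiguousarray(ld.R)
    diag = np.ascontiguousarray(np.diag(R))
    n = float(n_gwas) if n_gwas is not None else float(np.median(sumstats.n_gwas))
    if p_init is None:
        p_init = np.geomspace(P_INIT_RANGE[0], P_INIT_RANGE[1], n_chains)
    p_init = np.asarray(p_init, dtype=float)
    if h2_init is None:
        # Simple summary-statistic heritability: E[bhat_j^2] ~ beta_j^2 + 1/N.
        h2_init = float(np.clip(M * np.mean(bhat**2 - 1.0 / n), 0.01, 1.0))

    eigmin = float(np.linalg.eigvalsh(R)[0]) if M <= 2000 else None
    if eigmin is not None and eigmin < -1e-6:
        logger.warning("LD matrix smallest eigenvalue %.2e; jittering diagonal", eigmin)
        R = R + (1e-6 - eigmin) * np.eye(M)

    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(p_init))]

    all_draws, h2_traces, p_traces = [], [], []
    for c, (p0, cs) in enumerate(zip(p_init, chain_seeds)):
        draws, h2_tr, p_tr = _gibbs_chain(
            bhat, R, diag, n, float(p0), h2_init, n_iter, burn_in, thin,
            update_p, update_h2, cs,
        )
        all_draws.append(draws)
        h2_traces.append(h2_tr)
        p_traces.append(p_tr)
    h2_traces = np.asarray(h2_traces)
    p_traces = np.asarray(p_traces)
    n_keep = all_draws[0].shape[0]
    return PosteriorSamples(
        draws=np.concatenate(all_draws, axis=0),
        chain_id=np.repeat(np.arange(len(p_init)), n_keep),
        h2_per_chain=h2_traces[:, burn_in:].mean(axis=1),
        sparsity_per_chain=p_traces[:, burn_in:].mean(axis=1),
        h2_traces=h2_traces,
        p_traces=p_traces,
        snp_ids=list(sumstats.snp_ids),
    )


def chain_qc(samples: PosteriorSamples) -> PosteriorSamples:
    """Filter chains against cross-chain medians of h2 and sparsity.

    A chain is removed when its h2 estimate is below 0.7x the median h2 of
    all chains, or its sparsity estimate is below 0.5x / above 2x the
    median sparsity.  Burn-in and thinning have already been applied when
    the draws were stored, so the retained draws are simply those of the
    surviving chains (100 per chain).
    """
    h2 = samples.h2_per_chain
    p = samples.sparsity_per_chain
    med_h2 = np.median(h2)
    med_p = np.median(p)
    keep = (
        (h2 >= QC_H2_MIN_FRAC * med_h2)
        & (p >= QC_P_MIN_FRAC * med_p)
        & (p <= QC_P_MAX_FRAC * med_p)
    )
    if not keep.any():
        raise RuntimeError(
            "all chains removed by QC; inspect h2/sparsity traces for divergence"
        )
    if not keep.all():
        logger.info(
            "chain QC removed %d of %d chains", int((~keep).sum()), keep.size
        )
    mask = keep[samples.chain_id]
    report = {
        "kept_chains": np.flatnonzero(keep).tolist(),
        "removed_chains": np.flatnonzero(~keep).tolist(),
        "median_h2": float(med_h2),
        "median_sparsity": float(med_p),
    }
    return PosteriorSamples(
        draws=samples.draws[mask],
        chain_id=samples.chain_id[mask],
        h2_per_chain=h2[keep],
        sparsity_per_chain=p[keep],
        h2_traces=samples.h2_traces[keep],
        p_traces=samples.p_traces[keep],
        snp_ids=samples.snp_ids,
        qc_report=report,
    )
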