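"""Per-individual PGS posterior summaries, accuracy and coverage.

The posterior distribution of an individual's genetic liability g_i = x_i'b
is approximated by the B linear scores x_i' b~(1) ... x_i' b~(B) over the
posterior effect draws.  The PGS is the posterior mean, its uncertainty the
posterior variance (1/B denominator), and the credible interval the
equal-tailed empirical quantiles of the scores.  Individual accuracy is

    r_i^2 = 1 - var(g_i_hat) / var_beta(x_i'b),

the classic reliability of an estimated breeding value; the denominator is
the heritability in simulation (unit phenotype variance), the heritability
scaled by the training residual phenotype variance for real data, or a
Monte-Carlo estimate of the prior liability variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ancestry import PCBasis
from .bayes_pgs import PosteriorSamples, PriorSpec, RidgePosterior

__all__ = [
    "LiabilityPosterior",
    "AccuracyResult",
    "CalibrationResult",
    "posterior_liability",
    "individual_accuracy",
    "monte_carlo_denominator",
    "analytic_accuracy",
    "empirical_coverage",
]

DEFAULT_LEVEL = 0.90


@dataclass
class LiabilityPosterior:
    """Per-individual posterior mean/variance and credible bounds."""

    ghat: np.ndarray
    var_ghat: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    level: float = DEFAULT_LEVEL


@dataclass
class AccuracyResult:
    """Per-individual accuracy r_i^2 with the denominator that produced it."""

    r2: np.ndarray
    denominator: float | np.ndarray
    denominator_kind: str
    clamped: np.ndarray


@dataclass
class CalibrationResult:
    """Per-individual empirical coverage of nominal-level credible intervals."""

    coverage: np.ndarray
    n_replicates: int
    level: float


def posterior_liability(
    x: np.ndarray, samples: PosteriorSamples, level: float = DEFAULT_LEVEL
) -> LiabilityPosterior:
    """Summarize the liability posterior of each (standardized) genotype row.

    ``x`` must be centred/standardized with the training constants over the
    sampler's SNP set.  The variance uses the 1/B denominator and the
    credible bounds are the equal-tailed empirical quantiles, e.g. the 5%
    and 95% quantiles for the default 90% level.
    """
    if samples.B == 0:
        raise ValueError("no posterior draws (all chains removed by QC?)")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    scores = x @ samples.draws.T  # n x B
    ghat = scores.mean(axis=1)
    var_ghat = ((scores - ghat[:, None]) ** 2).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    ci_low, ci_high = np.quantile(scores, [alpha, 1.0 - alpha], axis=1)
    return LiabilityPosterior(
        ghat=ghat, var_ghat=var_ghat, ci_low=ci_low, ci_high=ci_high, level=level
    )


def individual_accuracy(
    lp: LiabilityPosterior,
    denominator: float | np.ndarray,
    denominator_kind: str = "h2_sim",
) -> AccuracyResult:
    """r_i^2 = 1 - var(g_i_hat)/denominator, clamped into [0, 1].

    ``denominator_kind`` records which prior-variance proxy was used:
    ``h2_sim`` (estimated heritability, unit phenotype variance),
    ``h2_times_resid_var`` (real data), or ``monte_carlo`` (per-individual
    prior draws).
    """
    den = np.asarray(denominator, dtype=float)
    if np.any(den <= 0):
        raise ValueError("accuracy denominator must be positive")
    raw = 1.0 - lp.var_ghat / den
    r2 = np.clip(raw, 0.0, 1.0)
    return AccuracyResult(
        r2=r2,
        denominator=denominator,
        denominator_kind=denominator_kind,
        clamped=(raw != r2),
    )


def monte_carlo_denominator(
    x: np.ndarray,
    h2: float,
    p_causal: float,
    n_draws: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Per-individual Monte-Carlo estimate of the prior liability variance.

    Draws standardized effects from the generating spike-and-slab prior
    (slab variance h2/(M p_causal)) and returns var over draws of x'b for
    each row of ``x``.
    """
    rng = np.random.default_rng(seed)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    M = x.shape[1]
    slab_sd = np.sqrt(h2 / (M * p_causal))
    mask = rng.random((n_draws, M)) < p_causal
    betas = np.where(mask, rng.normal(0.0, slab_sd, size=(n_draws, M)), 0.0)
    scores = x @ betas.T
    return scores.var(axis=1)


def analytic_accuracy(
    x: np.ndarray,
    basis: PCBasis | RidgePosterior,
    prior: PriorSpec,
    mode: str = "exact",
) -> np.ndarray:
    """Closed-form r_i^2 under the infinitesimal prior.

    Exact mode evaluates

        r_i^2 = 1 - sigma_e^2 sum_j (sigma_e^2/sigma_b^2 + lambda_j)^{-1}
                    (x'v_j)^2 / (sigma_b^2 x'x)

    including the null-space mass of x beyond the stored eigenpairs
    (treated as eigenvalue 0).  Approximate mode replaces the shrunken
    inverse with 1/lambda_j — the large-sample form whose distance term is
    the Mahalanobis ratio — and requires strictly positive eigenvalues.
    """
    if mode not in ("exact", "approximate"):
        raise ValueError("mode must be 'exact' or 'approximate'")
    if isinstance(basis, RidgePosterior):
        V, lam = basis.eigvecs, basis.eigvals
    else:
        V, lam = basis.loadings, basis.eigenvalues
    x = np.atleast_2d(np.asarray(x, dtype=float))
    s2 = project_sq = (x @ V) ** 2
    xtx = np.einsum("ij,ij->i", x, x)
    a = prior.sigma2_e / prior.sigma2_beta
    if mode == "exact":
        rest = np.maximum(xtx - project_sq.sum(axis=1), 0.0)
        quad = (s2 / (a + lam)).sum(axis=1) + rest / a
    else:
        if np.any(lam <= 0):
            raise ValueError(
                "approximate mode requires positive eigenvalues; truncate the basis"
            )
        quad = (s2 / lam).sum(axis=1)
    return 1.0 - prior.sigma2_e * quad / (prior.sigma2_beta * xtx)


def empirical_coverage(
    ci_low: np.ndarray,
    ci_high: np.ndarray,
    g_true: np.ndarray,
    level: float = DEFAULT_LEVEL,
) -> CalibrationResult:
    """Per-individual coverage over replicates.

    Inputs are (n_replicates x n_individuals) arrays; coverage_i is the
    fraction of replicates whose interval contains the true liability.
    """
    ci_low = np.atleast_2d(ci_low)
    ci_high = np.atleast_2d(ci_high)
    g_true = np.atleast_2d(g_true)
    if not (ci_low.shape == ci_high.shape == g_true.shape):
        raise ValueError("replicate arrays must share shape")
    if ci_low.shape[0] < 2:
        raise ValueError("coverage needs at least 2 replicates")
    inside = (g_true >= ci_low) & (g_true <= ci_high)
    return CalibrationResult(
        coverage=inside.mean(axis=0), n_replicates=ci_low.shape[0], level=level
    )
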