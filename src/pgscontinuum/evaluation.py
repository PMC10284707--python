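"""Population-level evaluation along the ancestry continuum.

Individuals are divided into equal-interval genetic-distance bins; within
each bin the squared correlation between PGS and outcome is computed with a
percentile-bootstrap confidence interval, alongside the bin means of the
individual-level accuracy, PGS and phenotype.  Global statistics are the
Pearson correlations of GD with accuracy, PGS and phenotype, and the
calibration slope from regressing the outcome on the PGS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContinuumReport",
    "bin_by_gd",
    "population_r2",
    "continuum_correlations",
    "slope_calibration",
    "plot_continuum",
]

DEFAULT_N_BINS = 20
DEFAULT_MIN_BIN_SIZE = 50
DEFAULT_N_BOOT = 1000


def _bin_assign(gd: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bins over [min(gd), max(gd)], right-most edge inclusive."""
    lo, hi = float(np.min(gd)), float(np.max(gd))
    edges = np.linspace(lo, hi, n_bins + 1)
    width = (hi - lo) / n_bins
    if width == 0:
        return np.zeros(gd.shape, dtype=int), edges
    idx = np.floor((gd - lo) / width).astype(int)
    return np.clip(idx, 0, n_bins - 1), edges


def bin_by_gd(
    gd: np.ndarray,
    ghat: np.ndarray,
    outcome: np.ndarray,
    r2_individual: np.ndarray | None = None,
    n_bins: int = DEFAULT_N_BINS,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """Equal-interval GD binning with within-bin R^2 and bootstrap CI.

    Bins with fewer than ``min_bin_size`` individuals are suppressed from
    the output (but logged); the outcome may be the true liability (in
    simulation) or the phenotype.
    """
    gd = np.asarray(gd, dtype=float)
    if not np.all(np.isfinite(gd)):
        raise ValueError("GD must be finite")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    idx, _ = _bin_assign(gd, n_bins)
    rng = np.random.default_rng(seed)
    rows = []
    n_suppressed = 0
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        if n < min_bin_size:
            n_suppressed += 1
            continue
        r2, lo, hi = population_r2(
            ghat[sel], outcome[sel], n_boot=n_boot,
            seed=int(rng.integers(2**31)),
        )
        rows.append(
            {
                "bin_index": b,
                "gd_mean": float(gd[sel].mean()),
                "n": n,
                "r2_pop": r2,
                "boot_low": lo,
                "boot_high": hi,
                "mean_r2_individual": (
                    float(np.mean(r2_individual[sel]))
                    if r2_individual is not None
                    else np.nan
                ),
                "mean_pgs": float(np.mean(ghat[sel])),
                "mean_pheno": float(np.mean(outcome[sel])),
            }
        )
    if n_suppressed:
        logger.info(
            "suppressed %d bins with fewer than %d individuals",
            n_suppressed,
            min_bin_size,
        )
    if not rows:
        raise ValueError("all bins below min_bin_size")
    return pd.DataFrame(rows)


def population_r2(
    ghat: np.ndarray,
    outcome: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Squared Pearson correlation with a percentile bootstrap 95% CI."""
    ghat = np.asarray(ghat, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    n = ghat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if np.var(ghat) == 0 or np.var(outcome) == 0:
        raise ValueError("zero-variance input")
    r2 = float(np.corrcoef(ghat, outcome)[0, 1] ** 2)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        gh, oc = ghat[take], outcome[take]
        if np.var(gh) == 0 or np.var(oc) == 0:
            boots[b] = r2
        else:
            boots[b] = np.corrcoef(gh, oc)[0, 1] ** 2
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return r2, float(lo), float(hi)


@dataclass
class ContinuumReport:
    """Global GD correlations (with two-sided p-values) and slope calibration."""

    cor_gd_accuracy: float
    p_gd_accuracy: float
    cor_gd_pgs: float
    p_gd_pgs: float
    cor_gd_pheno: float
    p_gd_pheno: float
    slope_calibration: float


def continuum_correlations(
    gd: np.ndarray,
    accuracy: np.ndarray,
    pgs: np.ndarray,
    phenotype: np.ndarray,
) -> ContinuumReport:
    """Pearson correlations of GD with accuracy, PGS and phenotype."""
    gd = np.asarray(gd, dtype=float)
    if gd.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    ra, pa = scipy.stats.pearsonr(gd, accuracy)
    rg, pg = scipy.stats.pearsonr(gd, pgs)
    rp, pp = scipy.stats.pearsonr(gd, phenotype)
    return ContinuumReport(
        cor_gd_accuracy=float(ra),
        p_gd_accuracy=float(pa),
        cor_gd_pgs=float(rg),
        p_gd_pgs=float(pg),
        cor_gd_pheno=float(rp),
        p_gd_pheno=float(pp),
        slope_calibration=slope_calibration(phenotype, pgs),
    )


def slope_calibration(outcome: np.ndarray, ghat: np.ndarray) -> float:
    """OLS slope of outcome on the posterior-mean PGS (intercept fitted).

    Under a calibrated Bayesian PGS, cov(outcome, ghat) = var(ghat), so the
    slope equals 1 in expectation.
    """
    ghat = np.asarray(ghat, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if np.var(ghat) == 0:
        raise ValueError("zero-variance PGS")
    return float(scipy.stats.linregress(ghat, outcome).slope)


def plot_continuum(
    gd: np.ndarray,
    accuracy: np.ndarray,
    bins: pd.DataFrame,
    path: str,
) -> None:
    """Static two-panel figure: GD vs accuracy scatter and binned R^2 curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].scatter(gd, accuracy, s=6, alpha=0.5)
    axes[0].set_xlabel("genetic distance")
    axes[0].set_ylabel("individual accuracy $\\hat r_i^2$")
    axes[1].errorbar(
        bins["gd_mean"],
        bins["r2_pop"],
        yerr=[
            bins["r2_pop"] - bins["boot_low"],
            bins["boot_high"] - bins["r2_pop"],
        ],
        fmt="o-",
        ms=3,
    )
    axes[1].set_xlabel("mean GD in bin")
    axes[1].set_ylabel("within-bin $R^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
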