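"""End-to-end orchestration: simulate -> GWAS -> sample -> QC -> score ->
distance -> evaluate -> calibrate, reproducible from one master seed."""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ancestry, bayes_pgs, evaluation, plink, scoring, simdata

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seed", "run_pipeline", "calibration_study"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed and name."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; every default is the study condition."""

    scenario: str = "gradient"  # "gradient" or "single"
    n_train: int = 5_000
    n_test: int = 200
    M: int = 2_000
    fst: float = 0.1
    h2: float = 0.25
    p_causal: float = 0.01
    n_replicates: int = 1
    # sampler
    n_chains: int = bayes_pgs.N_CHAINS
    n_iter: int = bayes_pgs.N_ITER
    burn_in: int = bayes_pgs.BURN_IN
    thin: int = bayes_pgs.THIN
    # PCA / distance
    J: int = ancestry.DEFAULT_J
    prune_window: int = 1000
    prune_step: int = 50
    prune_r2: float = 0.05
    # evaluation
    n_bins: int = evaluation.DEFAULT_N_BINS
    min_bin_size: int = evaluation.DEFAULT_MIN_BIN_SIZE
    n_boot: int = evaluation.DEFAULT_N_BOOT
    ci_level: float = scoring.DEFAULT_LEVEL
    seed: int = 0
    out_dir: str = "pgscontinuum_out"
    write_plink: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _make_panel(config: RunConfig) -> simdata.GenotypePanel:
    make = (
        simdata.gradient_model
        if config.scenario == "gradient"
        else simdata.single_ancestry_model
    )
    model = make(
        n_train=config.n_train,
        n_test=config.n_test,
        M=config.M,
        fst=config.fst,
        seed=stage_seed(config.seed, "simulate"),
    )
    panel = simdata.simulate_genotype_panel(model).drop_monomorphic()
    return panel


def calibration_study(
    n_replicates: int = 100,
    n_train: int = 5_000,
    n_test: int = 200,
    M: int = 2_000,
    h2: float = 0.25,
    p_causal: float = 0.01,
    scenario: str = "single",
    level: float = 0.90,
    seed: int = 0,
) -> dict:
    """Credible-interval calibration study with full refitting per replicate.

    For each replicate the genetic effects and noise are redrawn, a fresh
    GWAS and spike-and-slab fit are run, and the nominal-level credible
    interval of each test individual's genetic liability is checked against
    the true liability.  Returns per-individual coverage over replicates,
    the per-replicate calibration slopes (true liability regressed on the
    posterior-mean PGS), and per-replicate accuracy summaries.
    """
    config = RunConfig(
        scenario=scenario, n_train=n_train, n_test=n_test, M=M,
        h2=h2, p_causal=p_causal, seed=seed,
    )
    panel = _make_panel(config)
    ld = bayes_pgs.ld_from_panel(panel)
    X_test = simdata.standardize_genotypes(panel, rows=~panel.is_train)
    reps = simdata.simulate_replicates(
        panel, h2, p_causal, n_replicates=n_replicates,
        seed=stage_seed(seed, "phenotypes"),
    )
    ci_low, ci_high, g_true = [], [], []
    slopes, h2_estimates, widths, r2_individual = [], [], [], []
    for r, (arch, ph) in enumerate(reps):
        ss = bayes_pgs.marginal_gwas(panel, ph.y)
        samples = bayes_pgs.chain_qc(
            bayes_pgs.gibbs_spike_slab(ss, ld, seed=stage_seed(seed, f"gibbs-{r}"))
        )
        lp = scoring.posterior_liability(X_test, samples, level=level)
        g_test = ph.g[~panel.is_train]
        ci_low.append(lp.ci_low)
        ci_high.append(lp.ci_high)
        g_true.append(g_test)
        slopes.append(evaluation.slope_calibration(g_test, lp.ghat))
        h2_estimates.append(samples.h2_estimate)
        widths.append(lp.ci_high - lp.ci_low)
        r2_individual.append(
            scoring.individual_accuracy(lp, samples.h2_estimate).r2
        )
    cal = scoring.empirical_coverage(
        np.array(ci_low), np.array(ci_high), np.array(g_true), level=level
    )
    return {
        "coverage": cal.coverage,
        "mean_coverage": float(cal.coverage.mean()),
        "slopes": np.array(slopes),
        "h2_estimates": np.array(h2_estimates),
        "mean_ci_width": np.mean(widths, axis=0),
        "r2_individual": np.mean(r2_individual, axis=0),
        "n_replicates": n_replicates,
        "level": level,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns (and writes) a machine-readable summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("master seed %d", config.seed)
    for stage in ("simulate", "phenotypes", "gibbs-0", "bootstrap"):
        logger.info("stage seed %s = %d", stage, stage_seed(config.seed, stage))

    panel = _make_panel(config)
    if config.write_plink:
        plink.write_plink(panel, out / "panel")
    ld = bayes_pgs.ld_from_panel(panel)
    X_test = simdata.standardize_genotypes(panel, rows=~panel.is_train)
    test_ids = [
        i for i, t in zip(panel.individual_ids, panel.is_train) if not t
    ]

    # PCA basis on LD-pruned SNPs and genetic distances.
    pruned = ancestry.ld_prune(
        panel, config.prune_window, config.prune_step, config.prune_r2
    )
    basis = ancestry.fit_pca(panel, J=config.J, snp_ids=pruned)
    xb = ancestry.standardize_for_basis(panel, basis, rows=~panel.is_train)
    scores_pc = ancestry.project(xb, basis)
    gd = ancestry.genetic_distance(scores_pc)
    mahal = ancestry.mahalanobis_ratio(xb, basis)
    X_train_b = ancestry.standardize_for_basis(panel, basis, rows=panel.is_train)
    rel = ancestry.relationship_distance(xb, X_train_b)
    plink.write_distances(out / "distances.tsv", test_ids, gd, mahal, rel)
    plink.write_basis(out / "pca", basis, [panel.a1[panel.snp_ids.index(s)] for s in basis.snp_ids])

    reps = simdata.simulate_replicates(
        panel,
        config.h2,
        config.p_causal,
        n_replicates=config.n_replicates,
        seed=stage_seed(config.seed, "phenotypes"),
    )
    plink.write_phenotypes(out / "phenotypes.tsv", panel.individual_ids, [ph for _, ph in reps])

    ci_low, ci_high, g_true = [], [], []
    first_summary: dict = {}
    for r, (arch, ph) in enumerate(reps):
        ss = bayes_pgs.marginal_gwas(panel, ph.y)
        samples = bayes_pgs.gibbs_spike_slab(
            ss,
            ld,
            n_chains=config.n_chains,
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            thin=config.thin,
            seed=stage_seed(config.seed, f"gibbs-{r}"),
        )
        samples = bayes_pgs.chain_qc(samples)
        lp = scoring.posterior_liability(X_test, samples, level=config.ci_level)
        g_test = ph.g[~panel.is_train]
        ci_low.append(lp.ci_low)
        ci_high.append(lp.ci_high)
        g_true.append(g_test)
        if r == 0:
            acc = scoring.individual_accuracy(
                lp, samples.h2_estimate, denominator_kind="h2_sim"
            )
            plink.write_scores(out / "scores.tsv", test_ids, lp, acc, gd)
            report = evaluation.continuum_correlations(gd, acc.r2, lp.ghat, g_test)
            bins = evaluation.bin_by_gd(
                gd,
                lp.ghat,
                g_test,
                r2_individual=acc.r2,
                n_bins=config.n_bins,
                min_bin_size=min(config.min_bin_size, max(2, len(gd) // config.n_bins)),
                n_boot=config.n_boot,
                seed=stage_seed(config.seed, "bootstrap"),
            )
            bins.to_csv(out / "bins.tsv", sep="\t", index=False)
            first_summary = {
                "h2_estimate": samples.h2_estimate,
                "sparsity_estimate": float(np.median(samples.sparsity_per_chain)),
                "n_draws": samples.B,
                "qc": samples.qc_report,
                "cor_gd_accuracy": report.cor_gd_accuracy,
                "p_gd_accuracy": report.p_gd_accuracy,
                "cor_gd_pgs": report.cor_gd_pgs,
                "cor_gd_pheno": report.cor_gd_pheno,
                "slope_calibration": float(
                    evaluation.slope_calibration(g_test, lp.ghat)
                ),
            }

    summary = dict(first_summary)
    if config.n_replicates >= 2:
        cal = scoring.empirical_coverage(
            np.array(ci_low), np.array(ci_high), np.array(g_true),
            level=config.ci_level,
        )
        summary["mean_coverage"] = float(cal.coverage.mean())
        summary["n_replicates"] = cal.n_replicates
    else:
        logger.info("fewer than 2 replicates: calibration stage skipped")

    summary["seed"] = config.seed
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
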