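# pgscontinuum

Individual-level polygenic-score (PGS) accuracy across the genetic-ancestry
continuum.

Polygenic scores trained in one ancestry lose accuracy in others — but the
loss is not a property of discrete ancestry labels. It decays continuously,
individual by individual, with the genetic distance (GD) of each target
person from the PGS training cohort. `pgscontinuum` is a toolkit for
quantifying that decay at the level of a single individual. It is aimed at
statistical geneticists and methodologists who want per-individual
uncertainty and accuracy for PGS, and a fully simulated test bed for
studying PGS portability without access to biobank genotypes.

## What it computes

For a training cohort (genotypes `X_train`, phenotype `y_train`) and any
target individual with standardized genotypes `x_i`:

* **Posterior of genetic liability.** A spike-and-slab Gibbs sampler in
  the LDpred family (10 chains, automatic sparsity `p` and heritability
  `h2`, chain QC, burn-in and thinning) draws posterior effect vectors
  `beta~(1..B)` from GWAS summary statistics and the in-sample LD matrix;
  the scores `x_i' beta~(b)` approximate the posterior of `g_i = x_i' beta`.
  An exact infinitesimal (ridge) posterior via eigendecomposition is also
  provided.
* **PGS estimate and credible interval.** `ghat_i = mean_b(x_i' beta~(b))`,
  `var(ghat_i) = var_b(x_i' beta~(b))`, and the equal-tailed 90% interval
  from the 5%/95% empirical quantiles.
* **Individual accuracy.**
  `r_i^2 = 1 - var(ghat_i) / var_beta(x_i' beta)` — the reliability of an
  estimated breeding value, with the prior variance taken as the estimated
  heritability (simulation), heritability times residual phenotype
  variance (real data), or a Monte-Carlo prior variance.
* **Genetic distance.** `d_i = sqrt(sum_{j<=20} (x_i' v_j)^2)` on the
  training cohort's PC space (LD-pruned SNPs), plus the Mahalanobis-ratio
  and mean-squared-relationship alternatives.
* **Continuum evaluation.** Equal-interval GD bins with bootstrap R^2,
  Pearson correlations of GD with accuracy / PGS / phenotype, and the
  calibration slope of outcome on PGS.

A Balding–Nichols simulator generates structured genotype panels along an
admixture continuum (training-ancestry, gradient, and biobank-style
cohorts) and phenotypes `y = g + eps` with sparse standardized effects, so
every stage is testable end to end without external data.

## Worked example

```python
from pgscontinuum import RunConfig, run_pipeline

cfg = RunConfig(scenario="gradient", n_train=5_000, n_test=500, M=2_000,
                h2=0.25, p_causal=0.01, n_replicates=2, seed=7,
                out_dir="example_out")
summary = run_pipeline(cfg)
for k in ("h2_estimate", "sparsity_estimate", "n_draws",
          "cor_gd_accuracy", "slope_calibration", "mean_coverage"):
    print(k, "=", summary[k])
```

prints (exact values are reproducible from the seed):

```
h2_estimate = 0.20945696856685106
sparsity_estimate = 0.00995394822489766
n_draws = 1000
cor_gd_accuracy = -0.4648202478931022
slope_calibration = 0.9442096183300633
mean_coverage = 0.92
```

Reading: the sampler estimated `h2 ~ 0.21` (this replicate's realized
genetic variance; the generative target is 0.25) and a causal fraction of
~1.0% (truth 1%) from 1,000 retained posterior draws;
individual accuracy falls with genetic distance along the admixture
gradient (negative GD-accuracy correlation; averaging accuracy over more
replicates strengthens it); regressing true liability on the PGS gives a
slope of ~1; and the 90% credible intervals covered the true liability in
92% of individual x replicate pairs (2 replicates here; the calibration
study below uses 100). The run also writes per-individual
`scores.tsv` (PGS mean/variance, interval, accuracy, GD), `distances.tsv`,
`bins.tsv` and `summary.json` under `example_out/`.

The same stages are available as a CLI:
`pgscontinuum simulate|gwas|train|score|distance|evaluate|calibrate|run-all
--config cfg.yaml --seed 7 --out outdir`.

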