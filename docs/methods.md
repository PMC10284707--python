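# Methods

`pgscontinuum` implements an individual-level view of polygenic-score (PGS)
performance: instead of one accuracy number per ancestry group, every
target individual receives a posterior distribution of their genetic
liability, a credible interval, an accuracy estimate, and a genetic
distance (GD) from the PGS training cohort. This note records the model,
the algorithms, the simulation design, the numerical choices, and what the
packaged tests do and do not establish.

## Model

Phenotypes follow the standard additive model

    y_i = x_i' beta + eps_i,

where `x_i` is the M-vector of genotypes centred and scaled with the
allele frequency of the *training* population — the same constants are
applied to training and test individuals — `beta` is a vector of
standardized genetic effects, and `eps_i ~ N(0, sigma_e^2)`. Under a
random-effects view, `beta` is drawn from a prior, the PGS weights are the
posterior mean `beta_hat = E(beta | D)` given training data `D`, and an
individual's genetic liability `g_i = x_i' beta` has the posterior
summarized by:

* PGS estimate: `ghat_i = E(x_i' beta | D)`;
* PGS uncertainty: `var(ghat_i) = var(x_i' beta | D)`;
* credible interval: equal-tailed quantiles of the posterior of `x_i' beta`.

Individual PGS accuracy is the reliability of an estimated breeding value,

    r_i^2 = 1 - var(x_i' beta | D) / var_beta(x_i' beta),

i.e. one minus the ratio of posterior to prior liability variance. In
simulation the prior (genetic) variance is the heritability `h2` because
phenotypes have unit variance; for real data it is `h2` scaled by the
residual phenotypic variance of the training cohort; a per-individual
Monte-Carlo estimate over prior draws is available as a third denominator
(`monte_carlo`). `r_i^2` is clamped to [0, 1] with a flag, since a
Monte-Carlo posterior variance can exceed the denominator by chance. The
`h2` used by default is the sampler's own estimate, not the generative
truth (both are available to callers). A calibrated posterior also implies
that regressing the outcome (liability or phenotype) on `ghat` yields a
slope of 1, which the evaluation module reports as `slope_calibration`.

Because the intercept is not modelled, liabilities are identified only up
to a constant. All genotypes are centred to the training mean allele
count, and the simulated "true" liability is defined on the same centred
scale, `g_i = sum_m (x_im - 2 f_m) beta_m`; this pins posterior scores and
true liabilities to a common location so that interval coverage is
meaningful.

## Posterior inference

Two routes are implemented.

**Exact infinitesimal (ridge) posterior.** With `p(beta) = MVN(0,
sigma_b^2 I)` the posterior is Gaussian with

    mu_beta    = (sigma_e^2/sigma_b^2 I + X'X)^{-1} X'y
    Sigma_beta = sigma_e^2 (sigma_e^2/sigma_b^2 I + X'X)^{-1}

computed through the SVD of the training matrix; the M x M inverse is
never materialized. Quadratic forms `x' Sigma_beta x` are evaluated in the
eigenbasis, with the mass of `x` outside the stored eigenvectors treated
as eigenvalue zero. The closed-form accuracy

    r_i^2 = 1 - sigma_e^2 sum_j (sigma_e^2/sigma_b^2 + lambda_j)^{-1}
            (x'v_j)^2 / (sigma_b^2 x'x)

is available exactly and in a large-eigenvalue approximation that replaces
the shrunken inverse by `1/lambda_j`; the distance term of the
approximation, `sum_j (x'v_j)^2/lambda_j / (x'x)`, is the squared
Mahalanobis distance of the individual from the training centre on the
training PC space divided by the squared genotype norm.

**Spike-and-slab Gibbs sampler on summary statistics.** The sparse prior
is a mixture: with probability `p` an effect is drawn from
`N(0, h2/(M p))`, otherwise it is exactly zero. Inputs are marginal
standardized GWAS effects `bhat_j = x_j'y/N` and the in-sample LD matrix.
Each single-site update residualizes the marginal effect against the
current draw, computes the posterior inclusion probability from the
spike-and-slab conditional, and draws the effect from the slab conditional
when included. Hyperparameters are automatic: `p` receives a conjugate
Beta(1,1) update from the inclusion count each sweep, and `h2` is
recomputed from the current draw as `beta' R beta`. Ten chains start at
initial sparsity log-spaced between 1e-4 and 1; initial `h2` per chain is
the summary-statistic estimator `M * mean(bhat^2 - 1/N)` clamped to
[0.01, 1] (an intentionally crude value — it only seeds the first sweep).
Each chain runs 600 sweeps: 100 burn-in, then 500 sweeps thinned by 5,
giving 100 stored draws per chain. Chain QC removes chains whose `h2`
estimate falls below 0.7x the cross-chain median or whose sparsity falls
below 0.5x / above 2x the median sparsity; the retained draws (100-1,000)
form the posterior sample.

One numerical subtlety: columns standardized by the *binomial* scale
`sqrt(2f(1-f))` have empirical variance close to but not exactly 1. The
`LDMatrix` stores the exact correlation matrix (unit diagonal) plus the
per-SNP empirical scales, and the sampler reconstructs the raw
second-moment matrix from both, so its stationary distribution matches the
individual-data posterior exactly; the packaged conjugate-limit test
(slab-only sampler vs analytic ridge) holds at Monte-Carlo precision
because of this. Degenerate residualized effects need no special-casing —
the standard inclusion formula already handles them. If the LD matrix is
materially non-PSD a diagonal jitter is applied with a logged warning.

## Genetic distance

GD is the Euclidean distance of a target individual from the centre of the
training cohort on the training cohort's PC space:
`d_i = sqrt(sum_{j<=20} (x_i'v_j)^2)`, with `v_j` the top eigenvectors of
the LD-pruned, standardized training genotypes. Training projections are
mean-zero by construction, so no centring term is needed. The PCA SNP set
(pruned; greedy windowed pruning at r^2 > 0.05, window 1000 SNPs, step 50,
mirroring `plink --indep-pairwise`) deliberately differs from the PGS SNP
set (all SNPs); each `PCBasis` records its own SNP list and
standardization constants and projection refuses mismatched inputs.
Long-range-LD exclusion is a no-op for simulated panels (no such regions
are generated) but the pruning interface accepts any SNP subset for real
data. `J = 20` components by default; the basis truncation uses ARPACK
with a fixed start vector so runs are bit-reproducible.

Two companions: the Mahalanobis ratio above (nearly perfectly correlated
with GD, see below), and an alternative relationship-based distance, the
mean squared genetic relationship to the training individuals,
`mean_k (x'x_k/M)^2`. Note that this quantity *increases* with ancestry
divergence: a distant individual carries a systematic allele-frequency
offset and inflated standardized variance, which make its relationship
entries to training individuals larger in magnitude, so it is a distance,
not a similarity (the packaged gradient test asserts the increase).

## Simulation design

Genotypes follow the Balding-Nichols model: per-SNP ancestral frequencies
uniform on [0.1, 0.9]; population-k frequencies Beta-distributed around
the ancestral value with variance `F_k p (1-p)` (F = 0.1 by default for
both populations); individual dosages Binomial(2, q_i'p_snp) given the
individual's admixture row `q_i`. SNPs are unlinked, so the only LD is the
admixture-induced kind; no recombination maps, no sex chromosomes. SNPs
monomorphic in the training split are dropped with a logged warning before
standardization.

Three packaged cohort designs:

* `single_ancestry_model` — all individuals from one population; used for
  the calibration study (correctly specified, training-ancestry targets).
* `gradient_model` — test individuals span a two-endpoint admixture
  gradient linearly from 0 to 1. Training individuals sit on a *narrow
  cline* at endpoint A (admixture uniform on [0, 0.2]) rather than being
  exact replicates of one population: a perfectly homogeneous training
  cohort has pure noise PCs (its spectrum is at the Marchenko-Pastur
  edge), and projections onto noise directions cannot measure position
  along the continuum. Real training cohorts carry residual structure,
  and the narrow cline reproduces exactly that property; with it, GD
  correlates with the admixture fraction at R ~ 0.97 at the packaged
  scale.
* `biobank_model` — a target cohort shaped like a real biobank: 95% of
  test individuals share the training ancestry and 5% form a discrete
  cluster at the far endpoint. This is the composition on which the
  near-perfect GD/Mahalanobis-ratio concordance is claimed empirically;
  on a uniformly dispersed gradient the Pearson correlation between a
  quadratic quantity and a linear one saturates around 0.99 for purely
  geometric reasons, while the bulk-plus-distant-cluster geometry drives
  it above 0.995.

Phenotypes: a fraction `p_causal` of SNPs is causal (Bernoulli); causal
allele-count effects have variance `h2 / (var(x_m) M p_causal)` with
`var(x_m)` taken over all panel individuals, so `E var(g) = h2` and
`var(y) ~ 1` after adding `eps ~ N(0, 1-h2)`. The default replication
mode redraws both the effects and the noise each replicate (100 replicates
for coverage studies); a fixed-effects mode (`simulate_phenotypes` on one
architecture) exists for conditional-coverage experiments. All simulators
are bit-reproducible given a seed, and the pipeline derives every stage
seed deterministically from one master seed.

Default study conditions (also the defaults of `RunConfig` and of the
acceptance script): M = 2,000 SNPs, N_train = 5,000, 200 test
individuals, h2 = 0.25, p_causal = 0.01, 90% intervals, 100 replicates.
These are desk-scale stand-ins for biobank analyses (ca. 1M SNPs, 371k
training individuals); with far fewer, much stronger causal variants per
SNP, per-individual accuracy is higher than in real biobank work, but
calibration, slope, concordance and decay are properties of the model, not
of the scale. A second packaged scale mirrors a denser-signal setting
(h2 = 0.8, p_causal = 0.01, M = 2,000) for hyperparameter recovery.

## Evaluation

Individuals are split into equal-width GD bins over the observed range
(right-most edge inclusive; bins under `min_bin_size` = 50 are suppressed
from output but logged). Within-bin accuracy is the squared Pearson
correlation between PGS and outcome with a percentile bootstrap 95%
interval (1,000 resamples). Global statistics: Pearson correlations of GD
with accuracy, PGS and phenotype (two-sided t-approximation p-values; no
multiple-testing correction inside the library), and the calibration
slope. All individuals enter global statistics; suppression only affects
bin display. In simulation, the per-figure convention of averaging
per-individual quantities across replicates before correlating with GD is
followed by the packaged decay checks (single-replicate accuracy contains
architecture-specific scatter that is real signal but dilutes the
GD correlation).

## What the tests show, and what they do not

The packaged checks establish, at the study conditions above: nominal
coverage of the 90% liability intervals for training-ancestry targets
(~0.90 within binomial error); regression slope of liability on PGS ~ 1;
machine-precision agreement of the eigenbasis ridge posterior with dense
linear algebra; Monte-Carlo-precision agreement of the slab-only Gibbs
sampler with the analytic ridge posterior; GD/Mahalanobis concordance
above 0.995 on the biobank-style cohort; monotone accuracy decay and
credible-interval widening along the gradient; and recovery of `h2` within
25% at h2 = 0.8. They do not establish anything about real LD panels
(simulated SNPs are unlinked), about cross-ancestry causal-effect
heterogeneity or unshared causal variants (the accuracy estimator is an
upper bound when effects are not shared), about phenotypes with
covariates/confounding (simulated GWAS uses none), or about the behaviour
of the biobank-scale LDpred2 software, of which this sampler is an
independent re-implementation from its published description.

## Known limitations

* Dense LD handling only (M up to a few thousand); no banded/windowed LD.
* No LD-score-regression initialization; the summary-statistic `h2`
  initializer is deliberately simple and only affects the first sweep.
* GD requires the training PC basis to span the ancestry variation of the
  targets; for a training cohort with literally no structure the metric
  degenerates (see the gradient-model rationale above).
* The accuracy denominator in real-data mode depends on an externally
  supplied residual phenotype variance; the package does not model
  covariates itself.
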