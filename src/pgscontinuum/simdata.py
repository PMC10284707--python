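"""Structured genotype and phenotype simulation along an ancestry continuum.

Genotypes are generated under the Balding–Nichols model: each SNP has an
ancestral allele frequency p, and population k draws its frequency from a
Beta distribution with mean p and variance F_k * p * (1 - p).  Individuals
carry admixture proportions on the K-simplex and their allele counts are
Binomial(2, q_i . p_snp).  Phenotypes follow the standard additive model
y_i = g_i + eps_i with a Bernoulli-Gaussian ("spike and slab") genetic
architecture: a fraction p_causal of SNPs is causal, and causal effects on
the allele-count scale have variance h2 / (var(x_m) * M * p_causal) so that
the genetic liability has variance ~h2 and the phenotype variance ~1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AncestryModel",
    "GenotypePanel",
    "GeneticArchitecture",
    "PhenotypeSet",
    "gradient_model",
    "biobank_model",
    "single_ancestry_model",
    "simulate_genotype_panel",
    "standardize_genotypes",
    "simulate_architecture",
    "simulate_phenotypes",
    "simulate_replicates",
]


@dataclass
class AncestryModel:
    """Specification of the simulated cohort structure.

    ``admixture`` is an (n_train + n_test) x K matrix of admixture
    proportions (rows on the K-simplex); training rows come first.
    """

    K: int
    fst_vector: np.ndarray
    n_train: int
    n_test: int
    M: int
    admixture: np.ndarray
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        self.fst_vector = np.asarray(self.fst_vector, dtype=float)
        self.admixture = np.asarray(self.admixture, dtype=float)
        if self.K < 1:
            raise ValueError("invalid model: K must be >= 1")
        if self.M < 1:
            raise ValueError("invalid model: M must be >= 1")
        if self.fst_vector.shape != (self.K,):
            raise ValueError("fst_vector must have length K")
        if np.any(self.fst_vector < 0) or np.any(self.fst_vector >= 1):
            raise ValueError("fst entries must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral_freq_range must lie within (0, 1)")
        n = self.n_train + self.n_test
        if self.admixture.shape != (n, self.K):
            raise ValueError("admixture must be (n_train + n_test) x K")
        if np.any(self.admixture < 0) or not np.allclose(
            self.admixture.sum(axis=1), 1.0
        ):
            raise ValueError("admixture rows must be non-negative and sum to 1")


def gradient_model(
    n_train: int = 5_000,
    n_test: int = 200,
    M: int = 2_000,
    fst: float = 0.1,
    train_spread: float = 0.2,
    seed: int = 0,
) -> AncestryModel:
    """Two-endpoint admixture gradient.

    Test individual i has admixture proportion toward endpoint B ranging
    linearly from 0 to 1.  Training individuals sit on a narrow admixture
    cline at endpoint A (proportions uniform on [0, train_spread]): real
    PGS training cohorts carry residual ancestry structure, and without it
    the top training PCs are pure noise directions and the PC projection
    cannot measure distance along the continuum at all.
    """
    rng = np.random.default_rng([seed, 0xA2C])
    alpha = np.concatenate(
        [rng.uniform(0.0, train_spread, n_train), np.linspace(0.0, 1.0, n_test)]
    )
    q = np.column_stack([1.0 - alpha, alpha])
    return AncestryModel(
        K=2,
        fst_vector=np.array([fst, fst]),
        n_train=n_train,
        n_test=n_test,
        M=M,
        admixture=q,
        seed=seed,
    )


def biobank_model(
    n_train: int = 5_000,
    n_test: int = 1_000,
    M: int = 2_000,
    fst: float = 0.1,
    train_spread: float = 0.2,
    far_frac: float = 0.05,
    seed: int = 0,
) -> AncestryModel:
    """Biobank-style test cohort: training-ancestry bulk plus a distant cluster.

    Most test individuals share the training ancestry; a small minority
    forms a discrete cluster at the far admixture endpoint.  This mirrors
    the composition of real target biobanks, which are dominated by the
    training ancestry with distant-ancestry minorities concentrated at a
    common large genetic distance.
    """
    rng = np.random.default_rng([seed, 0xB10])
    n_far = int(round(far_frac * n_test))
    alpha = np.concatenate(
        [
            rng.uniform(0.0, train_spread, n_train),
            rng.uniform(0.0, train_spread, n_test - n_far),
            np.ones(n_far),
        ]
    )
    q = np.column_stack([1.0 - alpha, alpha])
    return AncestryModel(
        K=2,
        fst_vector=np.array([fst, fst]),
        n_train=n_train,
        n_test=n_test,
        M=M,
        admixture=q,
        seed=seed,
    )


def single_ancestry_model(
    n_train: int = 5_000,
    n_test: int = 200,
    M: int = 2_000,
    fst: float = 0.1,
    seed: int = 0,
) -> AncestryModel:
    """All individuals (training and test) from one homogeneous population."""
    q = np.ones((n_train + n_test, 1))
    return AncestryModel(
        K=1,
        fst_vector=np.array([fst]),
        n_train=n_train,
        n_test=n_test,
        M=M,
        admixture=q,
        seed=seed,
    )


@dataclass
class GenotypePanel:
    """Allele-count matrix with SNP/individual metadata and train/test split."""

    genotypes: np.ndarray  # n x M, entries in {0, 1, 2} (-1 = missing)
    snp_ids: list[str]
    individual_ids: list[str]
    is_train: np.ndarray
    a1: list[str] | None = None
    a2: list[str] | None = None
    admixture: np.ndarray | None = None
    train_freq: np.ndarray = field(init=False)
    monomorphic: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.is_train = np.asarray(self.is_train, dtype=bool)
        g_train = self.genotypes[self.is_train].astype(float)
        g_train[g_train < 0] = np.nan
        with np.errstate(invalid="ignore"):
            self.train_freq = np.nanmean(g_train, axis=0) / 2.0
        self.monomorphic = (self.train_freq <= 0.0) | (self.train_freq >= 1.0)
        if self.a1 is None:
            self.a1 = ["A"] * self.n_snps
        if self.a2 is None:
            self.a2 = ["G"] * self.n_snps

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_train(self) -> int:
        return int(self.is_train.sum())

    def drop_monomorphic(self) -> "GenotypePanel":
        """Drop SNPs monomorphic in the training set (standardization undefined)."""
        if not self.monomorphic.any():
            return self
        n_drop = int(self.monomorphic.sum())
        logger.warning("dropping %d SNPs monomorphic in training data", n_drop)
        keep = ~self.monomorphic
        return GenotypePanel(
            genotypes=self.genotypes[:, keep],
            snp_ids=[s for s, k in zip(self.snp_ids, keep) if k],
            individual_ids=self.individual_ids,
            is_train=self.is_train,
            a1=[s for s, k in zip(self.a1, keep) if k],
            a2=[s for s, k in zip(self.a2, keep) if k],
            admixture=self.admixture,
        )


def simulate_genotype_panel(model: AncestryModel) -> GenotypePanel:
    """Draw a genotype panel under the Balding–Nichols admixture model.

    Population-k frequencies are Beta-distributed around the ancestral
    frequency with variance fst_k * p * (1 - p); individual dosages are
    Binomial(2, q_i . p_snp).  Deterministic given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    lo, hi = model.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=model.M)

    pop_freq = np.empty((model.K, model.M))
    for k in range(model.K):
        f = model.fst_vector[k]
        if f == 0.0:
            pop_freq[k] = p_anc
        else:
            # Beta with mean p and variance f*p*(1-p): a = p(1-f)/f, b = (1-p)(1-f)/f
            a = p_anc * (1.0 - f) / f
            b = (1.0 - p_anc) * (1.0 - f) / f
            pop_freq[k] = rng.beta(a, b)

    ind_freq = model.admixture @ pop_freq  # n x M
    genotypes = rng.binomial(2, ind_freq).astype(np.int8)

    n = model.n_train + model.n_test
    is_train = np.zeros(n, dtype=bool)
    is_train[: model.n_train] = True
    return GenotypePanel(
        genotypes=genotypes,
        snp_ids=[f"snp{m}" for m in range(model.M)],
        individual_ids=[f"ind{i}" for i in range(n)],
        is_train=is_train,
        admixture=model.admixture,
    )


def standardize_genotypes(
    panel: GenotypePanel, rows: np.ndarray | None = None
) -> np.ndarray:
    """Centre and scale allele counts with training-frequency constants.

    Column j maps to (dosage - 2 f_j) / sqrt(2 f_j (1 - f_j)) where f_j is
    the allele frequency among training individuals; the same constants are
    applied to training and test rows.  Missing dosages (coded -1) are
    mean-imputed, i.e. standardized to zero.
    """
    if panel.monomorphic.any():
        bad = [s for s, m in zip(panel.snp_ids, panel.monomorphic) if m]
        raise ZeroDivisionError(
            f"monomorphic SNPs in training data (division by zero): {bad[:5]}"
        )
    g = panel.genotypes if rows is None else panel.genotypes[rows]
    f = panel.train_freq
    x = g.astype(float)
    x[x < 0] = np.nan
    x = (x - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    return np.nan_to_num(x, nan=0.0)


@dataclass
class GeneticArchitecture:
    """Sparse additive genetic architecture on the allele-count scale."""

    h2: float
    p_causal: float
    causal_mask: np.ndarray
    effects: np.ndarray
    seed: int = 0


def simulate_architecture(
    panel: GenotypePanel, h2: float, p_causal: float, seed: int = 0
) -> GeneticArchitecture:
    """Draw causal indicators and effect sizes.

    Causal SNPs are Bernoulli(p_causal); causal effects are
    N(0, h2 / (var(x_m) * M * p_causal)) with var(x_m) the allele-count
    variance over all panel individuals, so that E var(g) = h2.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    if not (0.0 < p_causal <= 1.0):
        raise ValueError("p_causal must lie in (0, 1] (p_causal=0 has no causal variants)")
    rng = np.random.default_rng(seed)
    M = panel.n_snps
    mask = rng.random(M) < p_causal
    var_x = panel.genotypes.astype(float).var(axis=0)
    var_x = np.where(var_x <= 0, np.nan, var_x)
    sd = np.sqrt(h2 / (var_x * M * p_causal))
    effects = np.where(mask, rng.normal(0.0, 1.0, size=M) * np.nan_to_num(sd), 0.0)
    return GeneticArchitecture(
        h2=h2, p_causal=p_causal, causal_mask=mask, effects=effects, seed=seed
    )


@dataclass
class PhenotypeSet:
    """One replicate of liability, noise and phenotype: y = g + eps exactly."""

    g: np.ndarray
    eps: np.ndarray
    y: np.ndarray
    replicate_id: int = 0


def _liability(panel: GenotypePanel, arch: GeneticArchitecture) -> np.ndarray:
    # Liability on training-centred allele counts: shares its location with
    # posterior scores computed from genotypes centred to training frequency.
    g = panel.genotypes.astype(float)
    g[g < 0] = np.nan
    centred = np.nan_to_num(g - 2.0 * panel.train_freq, nan=0.0)
    return centred @ arch.effects


def simulate_phenotypes(
    panel: GenotypePanel,
    arch: GeneticArchitecture,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[PhenotypeSet]:
    """Fixed-architecture mode: g computed once, eps redrawn per replicate."""
    rng = np.random.default_rng(seed)
    g = _liability(panel, arch)
    out = []
    for r in range(n_replicates):
        eps = rng.normal(0.0, np.sqrt(1.0 - arch.h2), size=g.shape[0])
        out.append(PhenotypeSet(g=g, eps=eps, y=g + eps, replicate_id=r))
    return out


def simulate_replicates(
    panel: GenotypePanel,
    h2: float,
    p_causal: float,
    n_replicates: int = 100,
    seed: int = 0,
) -> list[tuple[GeneticArchitecture, PhenotypeSet]]:
    """Default replication mode: redraw both effects and noise each replicate."""
    root = np.random.SeedSequence(seed)
    out = []
    for r, child in enumerate(root.spawn(n_replicates)):
        s1, s2 = child.generate_state(2) % (2**31)
        arch = simulate_architecture(panel, h2, p_causal, seed=int(s1))
        (ph,) = simulate_phenotypes(panel, arch, n_replicates=1, seed=int(s2))
        ph.replicate_id = r
        out.append((arch, ph))
    return out
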