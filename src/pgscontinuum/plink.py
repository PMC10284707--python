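"""PLINK1 bed/bim/fam and TSV input/output.

The bed codec implements the standard PLINK1 binary format directly:
magic bytes 0x6c 0x1b, mode byte 0x01 (variant-major), then ceil(N/4)
bytes per variant with two bits per individual, low bits first:

    00 -> 2 copies of A1      10 -> heterozygous (1 copy of A1)
    01 -> missing             11 -> 0 copies of A1

Dosages count the bim A1 allele; missing genotypes decode to -1, never 0.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ancestry import PCBasis
from .bayes_pgs import SummaryStats
from .simdata import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "read_plink",
    "write_plink",
    "write_phenotypes",
    "read_phenotypes",
    "write_sumstats",
    "read_sumstats",
    "harmonize_sumstats",
    "write_basis",
    "write_distances",
    "write_scores",
    "write_ld",
    "read_ld",
]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> A1 dosage (-1 = missing)
_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix: str | Path, is_train: np.ndarray | None = None) -> GenotypePanel:
    """Read a bed/bim/fam triplet into a GenotypePanel.

    ``is_train`` marks the training split (defaults to all individuals);
    training allele frequencies are recomputed from those rows.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _MAGIC:
        raise ValueError(
            f"{prefix}.bed: bad magic/mode bytes {raw[:3]!r} "
            "(expected variant-major PLINK1 bed)"
        )
    bytes_per_var = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * bytes_per_var:
        raise ValueError(f"{prefix}.bed truncated: {body.size} body bytes, "
                         f"expected {m * bytes_per_var}")
    codes = np.empty((m, bytes_per_var * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body.reshape(m, bytes_per_var) >> (2 * shift)) & 0b11
    geno = _DECODE[codes[:, :n]].T.copy()  # n x m
    n_missing = int((geno < 0).sum())
    if n_missing:
        logger.warning("%s.bed: %d missing genotypes", prefix, n_missing)
    if is_train is None:
        is_train = np.ones(n, dtype=bool)
    return GenotypePanel(
        genotypes=geno,
        snp_ids=bim["snp"].tolist(),
        individual_ids=fam["iid"].tolist(),
        is_train=np.asarray(is_train, dtype=bool),
        a1=bim["a1"].tolist(),
        a2=bim["a2"].tolist(),
    )


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as variant-major PLINK1 bed/bim/fam (chromosome 1,
    1-based positions, cM 0)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = panel.n_individuals, panel.n_snps
    bim = pd.DataFrame(
        {
            "chrom": 1,
            "snp": panel.snp_ids,
            "cm": 0,
            "pos": np.arange(1, m + 1),
            "a1": panel.a1,
            "a2": panel.a2,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.individual_ids,
            "iid": panel.individual_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    lut = np.empty(256, dtype=np.uint8)  # dosage byte -> 2-bit code
    for dos, code in _ENCODE.items():
        lut[dos & 0xFF] = code
    codes = lut[panel.genotypes.T.astype(np.int8).view(np.uint8)]  # m x n
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def write_phenotypes(path: str | Path, iids: list[str], replicates: list) -> None:
    """Phenotype TSV with columns IID, replicate, g, y."""
    rows = []
    for ph in replicates:
        for iid, g, y in zip(iids, ph.g, ph.y):
            rows.append((iid, ph.replicate_id, g, y))
    pd.DataFrame(rows, columns=["IID", "replicate", "g", "y"]).to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"IID": str})


def write_sumstats(path: str | Path, ss: SummaryStats, a1: list[str]) -> None:
    """Summary-statistics TSV with columns SNP, A1, BETA_STD, N."""
    pd.DataFrame(
        {"SNP": ss.snp_ids, "A1": a1, "BETA_STD": ss.beta_gwas, "N": ss.n_gwas}
    ).to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str})


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def harmonize_sumstats(panel: GenotypePanel, table: pd.DataFrame) -> SummaryStats:
    """Match a summary-statistics table to the panel by SNP id and allele.

    Effects whose A1 equals the panel A2 are sign-flipped; strand-ambiguous
    A/T and C/G SNPs are dropped with a logged count, as are ids absent
    from the panel.
    """
    by_id = {s: i for i, s in enumerate(panel.snp_ids)}
    beta = np.full(panel.n_snps, np.nan)
    n = np.full(panel.n_snps, np.nan)
    n_ambiguous = n_unmatched = 0
    for rec in table.itertuples(index=False):
        i = by_id.get(rec.SNP)
        if i is None:
            n_unmatched += 1
            continue
        pa1, pa2 = panel.a1[i], panel.a2[i]
        if _COMPLEMENT.get(pa1) == pa2:
            n_ambiguous += 1
            continue
        if rec.A1 == pa1:
            beta[i] = rec.BETA_STD
        elif rec.A1 == pa2:
            beta[i] = -rec.BETA_STD
        else:
            n_unmatched += 1
            continue
        n[i] = rec.N
    if n_ambiguous or n_unmatched:
        logger.info(
            "harmonization dropped %d ambiguous and %d unmatched records",
            n_ambiguous,
            n_unmatched,
        )
    keep = np.isfinite(beta)
    return SummaryStats(
        snp_ids=[s for s, k in zip(panel.snp_ids, keep) if k],
        beta_gwas=beta[keep],
        n_gwas=n[keep],
    )


def write_ld(prefix: str | Path, ld) -> None:
    """LD matrix as a binary .npy with a plain-text SNP-id sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(f"{prefix}.npy", ld.R)
    if ld.diag_scale is not None:
        np.save(f"{prefix}_scale.npy", ld.diag_scale)
    Path(f"{prefix}.snps.txt").write_text("\n".join(ld.snp_ids) + "\n")


def read_ld(prefix: str | Path):
    from .bayes_pgs import LDMatrix

    prefix = Path(prefix)
    scale_path = Path(f"{prefix}_scale.npy")
    return LDMatrix(
        R=np.load(f"{prefix}.npy"),
        snp_ids=Path(f"{prefix}.snps.txt").read_text().splitlines(),
        diag_scale=np.load(scale_path) if scale_path.exists() else None,
    )


def write_basis(prefix: str | Path, basis: PCBasis, a1: list[str]) -> None:
    """Save a PCBasis as flashpca-style text files.

    ``<prefix>_loadings.tsv`` (SNP, A1, one weight column per PC),
    ``<prefix>_eigenvalues.tsv`` and ``<prefix>_meansd.tsv``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    load = pd.DataFrame({"SNP": basis.snp_ids, "A1": a1})
    for j in range(basis.J):
        load[f"PC{j + 1}"] = basis.loadings[:, j]
    load.to_csv(f"{prefix}_loadings.tsv", sep="\t", index=False)
    pd.DataFrame({"eigenvalue": basis.eigenvalues}).to_csv(
        f"{prefix}_eigenvalues.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"SNP": basis.snp_ids, "mean": basis.snp_means, "sd": basis.snp_sds}
    ).to_csv(f"{prefix}_meansd.tsv", sep="\t", index=False)


def write_distances(
    path: str | Path,
    iids: list[str],
    gd: np.ndarray,
    mahal: np.ndarray | None = None,
    rel: np.ndarray | None = None,
) -> None:
    df = pd.DataFrame({"IID": iids, "GD": gd})
    if mahal is not None:
        df["MAHAL_RATIO"] = mahal
    if rel is not None:
        df["REL_DIST"] = rel
    df.to_csv(path, sep="\t", index=False)


def write_scores(path: str | Path, iids: list[str], lp, acc, gd=None) -> None:
    """Per-individual results TSV (IID, PGS mean/var, CI, accuracy, GD)."""
    df = pd.DataFrame(
        {
            "IID": iids,
            "PGS_MEAN": lp.ghat,
            "PGS_VAR": lp.var_ghat,
            "CI_LOW": lp.ci_low,
            "CI_HIGH": lp.ci_high,
            "R2": acc.r2,
            "R2_CLAMPED": acc.clamped.astype(int),
        }
    )
    if gd is not None:
        df["GD"] = gd
    df.to_csv(path, sep="\t", index=False)
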