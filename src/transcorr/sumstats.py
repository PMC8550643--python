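"""GWAS summary statistics: marginal per-SNP regression and the text format.

Association is a simple linear regression of the phenotype on each
variance-standardized dosage column independently, so the estimated effect
sits on the same standardized scale as the simulated architecture and
Z^2 follows the LD-score identity E[z_i^2] = 1 + N h^2 ell_i / M under the
generative model.

Files are whitespace-delimited with the LDSC/Popcorn-style header
``SNP A1 A2 af N beta SE``; A1 is the dosage-counted allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import PhenotypeSet, normalize_genotypes
from .popgen import GenotypeDataset

__all__ = ["SummaryStats", "run_gwas", "write_sumstats", "read_sumstats"]

_COLUMNS = ["SNP", "A1", "A2", "af", "N", "beta", "SE"]


@dataclass
class SummaryStats:
    """Per-SNP marginal association results for one population."""

    snp_ids: np.ndarray
    beta_hat: np.ndarray
    se: np.ndarray
    af: np.ndarray
    n: int
    population: str = "pop"

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.af = np.asarray(self.af, dtype=float)
        if not (self.snp_ids.size == self.beta_hat.size == self.se.size == self.af.size):
            raise ValueError("summary-statistic columns must share a length")
        if np.any(self.se <= 0.0):
            raise ValueError("standard errors must be strictly positive")

    @property
    def z(self) -> np.ndarray:
        return self.beta_hat / self.se

    @property
    def n_snps(self) -> int:
        return int(self.snp_ids.size)

    def select(self, index: np.ndarray) -> "SummaryStats":
        return SummaryStats(
            snp_ids=self.snp_ids[index],
            beta_hat=self.beta_hat[index],
            se=self.se[index],
            af=self.af[index],
            n=self.n,
            population=self.population,
        )


def run_gwas(
    data: GenotypeDataset,
    phen: PhenotypeSet,
    standardized: np.ndarray | None = None,
) -> SummaryStats:
    """Marginal regression of the phenotype on every standardized SNP.

    For SNP i with sample correlation r_i between dosage and phenotype,
    the standardized-scale OLS slope is b_i = r_i * sd(Y), its standard
    error sqrt((1 - r_i^2)/(n-2)) * sd(Y), hence
    z_i = r_i sqrt(n-2)/sqrt(1-r_i^2).  |z| is capped at sqrt(n-2)
    (the |r| -> 1 degenerate fit) with a warning.

    ``standardized`` may carry a precomputed ``normalize_genotypes(data)``
    matrix to avoid recomputation inside pipelines.
    """
    y = np.asarray(phen.values, dtype=float)
    n = y.size
    if data.n_individuals != n:
        raise ValueError("genotypes and phenotypes disagree on sample size")
    if n < 30:
        raise ValueError("GWAS requires n >= 30")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes contain non-finite values")
    if np.any((data.freqs <= 0.0) | (data.freqs >= 1.0)):
        raise ValueError("monomorphic SNPs must be filtered before GWAS")
    x = normalize_genotypes(data) if standardized is None else standardized
    yc = y - y.mean()
    sd_y = float(np.sqrt((yc @ yc) / n))
    if sd_y == 0.0:
        raise ValueError("phenotype has zero variance")
    # columns of x have exactly zero mean; empirical column SD for exact r
    col_sd = np.sqrt(np.einsum("ij,ij->j", x, x, dtype=np.float64) / n)
    if np.any(col_sd == 0.0):
        raise ValueError("zero-variance SNP column encountered")
    r = (x.T @ yc.astype(x.dtype)).astype(np.float64) / (n * col_sd * sd_y)
    r = np.clip(r, -1.0, 1.0)
    z_cap = np.sqrt(n - 2.0)
    beta_hat = r * sd_y
    with np.errstate(divide="ignore"):
        z = r * z_cap / np.sqrt(np.maximum(1.0 - r * r, 1e-300))
    capped = np.abs(z) > z_cap
    if capped.any():
        warnings.warn(
            f"{int(capped.sum())} SNP(s) fit the phenotype almost perfectly; "
            f"z capped at sqrt(n-2)",
            stacklevel=2,
        )
        np.clip(z, -z_cap, z_cap, out=z)
    # se chosen so that z = beta_hat / se holds exactly, including at caps
    null_se = sd_y / z_cap
    se = np.where(z != 0.0, np.abs(beta_hat) / np.abs(np.where(z == 0.0, 1.0, z)), null_se)
    return SummaryStats(
        snp_ids=data.snp_ids,
        beta_hat=beta_hat,
        se=se,
        af=data.freqs,
        n=n,
        population=data.population,
    )


def write_sumstats(stats: SummaryStats, path) -> None:
    """Whitespace-delimited summary statistics with header SNP A1 A2 af N beta SE."""
    df = pd.DataFrame(
        {
            "SNP": stats.snp_ids,
            "A1": "A",
            "A2": "G",
            "af": stats.af,
            "N": stats.n,
            "beta": stats.beta_hat,
            "SE": stats.se,
        }
    )
    df.to_csv(path, sep=" ", index=False, float_format="%.6g")


def read_sumstats(path, population: str = "pop") -> SummaryStats:
    """Read the summary-statistics text format (gzip-transparent)."""
    df = pd.read_csv(path, sep=r"\s+")
    for col in _COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{col} column absent")
    if (df["SE"] <= 0).any():
        raise ValueError("SE column contains non-positive values")
    n_vals = df["N"].unique()
    if n_vals.size != 1:
        raise ValueError("N column must be constant within one file")
    return SummaryStats(
        snp_ids=df["SNP"].to_numpy(dtype=str),
        beta_hat=df["beta"].to_numpy(dtype=float),
        se=df["SE"].to_numpy(dtype=float),
        af=df["af"].to_numpy(dtype=float),
        n=int(n_vals[0]),
        population=population,
    )
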