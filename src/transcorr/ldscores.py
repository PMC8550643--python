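"""LD scores from external reference panels.

For each SNP i the within-population score sums bias-corrected squared
LD correlations over a symmetric window of W SNPs on either side,

    ell_i = sum_j  r_hat(i,j)^2 - (1 - r_hat(i,j)^2) / (L - 2),

including the self term (which contributes exactly 1).  The cross-population
score sums the product of the two panels' correlations,

    impact mode:  ellx_i = sum_j r1(i,j) r2(i,j)
    effect mode:  ellx_i = sum_j r1(i,j) r2(i,j) sigma1_j sigma2_j / (c1 c2)

with sigma_k = sqrt(2 f_k (1-f_k)) from the panel allele frequencies and
c_k the root-mean-square sigma over the analysis SNP set; the effect-mode
weight maps the per-allele effect covariance onto the shared h^2/M variance
parameterization.  Cross products need no small-sample correction because
the two panels are independent samples.

Windows are in SNP-index units (the simulator has no physical map) and the
window is clipped at the ends of the SNP array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen import GenotypeDataset

__all__ = [
    "LDScores",
    "ld_correlation_window",
    "within_scores",
    "cross_scores",
    "compute_ld_scores",
    "write_scores",
    "read_scores",
]

_HEADER = ["SNP", "af1", "af2", "ell1", "ell2", "ellx_impact", "ellx_effect"]


@dataclass
class LDScores:
    """Per-SNP within- and cross-population LD scores."""

    snp_ids: np.ndarray
    af1: np.ndarray
    af2: np.ndarray
    ell1: np.ndarray
    ell2: np.ndarray
    ellx_impact: np.ndarray
    ellx_effect: np.ndarray
    window: int
    L1: int
    L2: int

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        for name in ("af1", "af2", "ell1", "ell2", "ellx_impact", "ellx_effect"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size != self.snp_ids.size:
                raise ValueError(f"{name} length does not match SNP ids")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n_snps(self) -> int:
        return int(self.snp_ids.size)

    def ellx(self, mode: str) -> np.ndarray:
        if mode == "impact":
            return self.ellx_impact
        if mode == "effect":
            return self.ellx_effect
        raise ValueError("mode must be 'impact' or 'effect'")

    def select(self, index: np.ndarray) -> "LDScores":
        return LDScores(
            snp_ids=self.snp_ids[index],
            af1=self.af1[index],
            af2=self.af2[index],
            ell1=self.ell1[index],
            ell2=self.ell2[index],
            ellx_impact=self.ellx_impact[index],
            ellx_effect=self.ellx_effect[index],
            window=self.window,
            L1=self.L1,
            L2=self.L2,
        )


def _standardized_columns(panel: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Columns scaled so r(i,j) = z_i . z_j; monomorphic columns zeroed."""
    x = panel.dosages.astype(np.float64)
    x -= x.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", x, x))
    mono = norms == 0.0
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} SNP(s) monomorphic in the reference panel; "
            "their LD correlations are set to 0",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        x /= np.where(mono, 1.0, norms)
    x[:, mono] = 0.0
    return x, mono


def _correlation_bands(panel: GenotypeDataset, window: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Pearson correlations by lag: bands[k-1][i] = r(i, i+k), k = 1..window."""
    z, mono = _standardized_columns(panel)
    bands = []
    m = panel.n_snps
    for k in range(1, min(window, m - 1) + 1):
        bands.append(np.einsum("ij,ij->j", z[:, :-k], z[:, k:]))
    return bands, mono


def ld_correlation_window(panel: GenotypeDataset, i: int, W: int) -> np.ndarray:
    """Correlations r(i, j) for j in [i-W, i+W] clipped to the SNP array."""
    if panel.n_individuals < 3:
        raise ValueError("panel needs at least 3 individuals")
    z, mono = _standardized_columns(panel)
    lo, hi = max(0, i - W), min(panel.n_snps, i + W + 1)
    r = z[:, lo:hi].T @ z[:, i]
    if not mono[i]:
        r[i - lo] = 1.0  # exact self correlation
    return np.clip(r, -1.0, 1.0)


def _corrected_sq(r: np.ndarray, L: int) -> np.ndarray:
    r2 = r * r
    return r2 - (1.0 - r2) / (L - 2.0)


def within_scores(panel: GenotypeDataset, W: int) -> np.ndarray:
    """Bias-corrected within-population LD scores over a +/-W SNP window."""
    L = panel.n_individuals
    if L <= 2:
        raise ValueError("within-population scores require L > 2")
    bands, mono = _correlation_bands(panel, W)
    m = panel.n_snps
    ell = np.ones(m)  # self term
    for k, r in enumerate(bands, start=1):
        a = _corrected_sq(r, L)
        ell[: m - k] += a
        ell[k:] += a
    return ell


def cross_scores(
    panel1: GenotypeDataset,
    panel2: GenotypeDataset,
    mode: str,
    W: int,
) -> np.ndarray:
    """Cross-population LD scores; see module docstring for the two modes."""
    if panel1.n_snps != panel2.n_snps or np.any(panel1.snp_ids != panel2.snp_ids):
        raise ValueError("reference panels must share the same SNP set and order")
    if mode not in ("impact", "effect"):
        raise ValueError("mode must be 'impact' or 'effect'")
    bands1, _ = _correlation_bands(panel1, W)
    bands2, _ = _correlation_bands(panel2, W)
    m = panel1.n_snps
    if mode == "effect":
        s1 = np.sqrt(2.0 * panel1.freqs * (1.0 - panel1.freqs))
        s2 = np.sqrt(2.0 * panel2.freqs * (1.0 - panel2.freqs))
        w = s1 * s2
        denom = np.sqrt(np.mean(s1 * s1) * np.mean(s2 * s2))
        w = w / denom if denom > 0 else np.zeros(m)
    else:
        w = np.ones(m)
    ellx = w.copy()  # self term: r1 * r2 = 1, weighted by own w
    for k in range(len(bands1)):
        prod = bands1[k] * bands2[k]
        ellx[: m - k - 1] += prod * w[k + 1 :]
        ellx[k + 1 :] += prod * w[: m - k - 1]
    return ellx


def compute_ld_scores(
    panel1: GenotypeDataset, panel2: GenotypeDataset, W: int = 100
) -> LDScores:
    """All four score columns from a pair of reference panels."""
    return LDScores(
        snp_ids=panel1.snp_ids,
        af1=panel1.freqs,
        af2=panel2.freqs,
        ell1=within_scores(panel1, W),
        ell2=within_scores(panel2, W),
        ellx_impact=cross_scores(panel1, panel2, "impact", W),
        ellx_effect=cross_scores(panel1, panel2, "effect", W),
        window=W,
        L1=panel1.n_individuals,
        L2=panel2.n_individuals,
    )


def write_scores(scores: LDScores, path) -> None:
    """TSV with '#key=value' metadata lines and the 7-column score table."""
    with open(path, "w") as fh:
        fh.write(f"#window={scores.window}\n#L1={scores.L1}\n#L2={scores.L2}\n")
        pd.DataFrame(
            {
                "SNP": scores.snp_ids,
                "af1": scores.af1,
                "af2": scores.af2,
                "ell1": scores.ell1,
                "ell2": scores.ell2,
                "ellx_impact": scores.ellx_impact,
                "ellx_effect": scores.ellx_effect,
            }
        ).to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_scores(path) -> LDScores:
    meta = {"window": 0, "L1": 0, "L2": 0}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            if key in meta:
                meta[key] = int(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    if list(df.columns) != _HEADER:
        raise ValueError(f"scores header must be exactly {' '.join(_HEADER)}")
    return LDScores(
        snp_ids=df["SNP"].to_numpy(dtype=str),
        af1=df["af1"].to_numpy(),
        af2=df["af2"].to_numpy(),
        ell1=df["ell1"].to_numpy(),
        ell2=df["ell2"].to_numpy(),
        ellx_impact=df["ellx_impact"].to_numpy(),
        ellx_effect=df["ellx_effect"].to_numpy(),
        window=meta["window"],
        L1=meta["L1"],
        L2=meta["L2"],
    )
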