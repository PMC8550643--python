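"""Weighted-likelihood estimation of heritability and genetic correlation.

Under the polygenic model the marginal Z statistics are approximately
normal per SNP,

    z_ki ~ N(0, 1 + N_k h_k^2 ell_ki / M),                  k = 1, 2
    Cov(z_1i, z_2i) = sqrt(N1 N2) rho sqrt(h1^2 h2^2) ellx_i / M,

so heritabilities are estimated by maximizing the product of per-SNP
normal likelihoods over h^2 in [0,1], and the genetic correlation by
maximizing the bivariate-normal likelihood over rho in [-1,1] with the
heritabilities held at their first-stage estimates.  Per-SNP weights
1/max(ell, 1) down-weight SNPs whose signal is double-counted through LD.

Standard errors come from a delete-one-block jackknife over contiguous
SNP blocks, which respects the local LD dependence between SNPs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import minimize_scalar

from .ldscores import LDScores
from .sumstats import SummaryStats

__all__ = [
    "LikelihoodConfig",
    "FitResult",
    "fit_heritability",
    "fit_correlation",
    "jackknife_se",
    "full_fit",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_H_EPS = 1e-6  # heritability below this is treated as boundary zero


@dataclass(frozen=True)
class LikelihoodConfig:
    mode: str = "impact"
    weights: str = "inverse_ld"
    h_bounds: tuple[float, float] = (0.0, 1.0)
    rho_bounds: tuple[float, float] = (-1.0, 1.0)
    optimizer_tol: float = 1e-6
    jackknife_blocks: int = 20

    def __post_init__(self) -> None:
        if self.mode not in ("impact", "effect"):
            raise ValueError("mode must be 'impact' or 'effect'")
        if self.weights not in ("inverse_ld", "uniform"):
            raise ValueError("weights must be 'inverse_ld' or 'uniform'")
        if self.optimizer_tol <= 0:
            raise ValueError("optimizer tolerance must be positive")
        if self.jackknife_blocks < 2:
            raise ValueError("jackknife needs at least 2 blocks")


@dataclass
class FitResult:
    """Point estimates, jackknife SEs and convergence metadata."""

    h1_sq_hat: float
    h2_sq_hat: float
    rho_hat: float
    se_h1: float
    se_h2: float
    se_rho: float
    mode: str
    loglik: float
    converged: bool
    n_snps_used: int
    rho_defined: bool = True  # False when a zero heritability short-circuits rho

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, payload: str) -> "FitResult":
        return cls(**json.loads(payload))


def _snp_weights(ell: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "inverse_ld":
        return 1.0 / np.maximum(ell, 1.0)
    return np.ones_like(ell)


def _h_objective(h: float, z2: np.ndarray, ell: np.ndarray, n: int, m: int, w: np.ndarray) -> float:
    v = 1.0 + n * h * ell / m
    return float(np.sum(w * (np.log(v) + z2 / v)))  # -2*loglik up to constants


def fit_heritability(
    stats: SummaryStats,
    ell: np.ndarray,
    M: int,
    config: LikelihoodConfig = LikelihoodConfig(),
) -> tuple[float, float]:
    """Bounded 1-D maximum of the weighted per-SNP normal likelihood.

    Returns (h_sq_hat, loglik at the maximum).
    """
    z = stats.z
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite Z statistics")
    if M < 50:
        raise ValueError("need at least 50 SNPs for a stable fit")
    if z.size != np.asarray(ell).size:
        raise ValueError("summary statistics and LD scores are not aligned")
    ell = np.asarray(ell, dtype=float)
    w = _snp_weights(ell, config.weights)
    z2 = z * z
    res = minimize_scalar(
        _h_objective,
        bounds=config.h_bounds,
        args=(z2, ell, stats.n, M, w),
        method="bounded",
        options={"xatol": config.optimizer_tol},
    )
    if not res.success:
        raise RuntimeError(f"heritability optimizer failed: {res.message}")
    h = float(res.x)
    loglik = -0.5 * (res.fun + float(np.sum(w)) * _LOG_2PI)
    return h, loglik


def _rho_objective(
    rho: float,
    z1: np.ndarray,
    z2: np.ndarray,
    v1: np.ndarray,
    v2: np.ndarray,
    cov_unit: np.ndarray,
    w: np.ndarray,
) -> float:
    c = rho * cov_unit
    det = v1 * v2 - c * c
    if np.any(det <= 0.0):
        return np.inf  # rejected: covariance not positive definite here
    quad = (v2 * z1 * z1 - 2.0 * c * z1 * z2 + v1 * z2 * z2) / det
    return float(np.sum(w * (np.log(det) + quad)))


def fit_correlation(
    stats1: SummaryStats,
    stats2: SummaryStats,
    scores: LDScores,
    h1_sq_hat: float,
    h2_sq_hat: float,
    M: int,
    config: LikelihoodConfig = LikelihoodConfig(),
) -> tuple[float, float]:
    """Maximize the bivariate-normal likelihood over rho with h^2 fixed."""
    for h in (h1_sq_hat, h2_sq_hat):
        if not (0.0 <= h <= 1.0):
            raise ValueError("heritability estimates must lie in [0, 1]")
    if np.any(stats1.snp_ids != stats2.snp_ids) or np.any(stats1.snp_ids != scores.snp_ids):
        raise ValueError("summary statistics and scores must share SNP ids and order")
    z1, z2 = stats1.z, stats2.z
    v1 = 1.0 + stats1.n * h1_sq_hat * scores.ell1 / M
    v2 = 1.0 + stats2.n * h2_sq_hat * scores.ell2 / M
    cov_unit = (
        np.sqrt(stats1.n * stats2.n)
        * np.sqrt(h1_sq_hat * h2_sq_hat)
        * scores.ellx(config.mode)
        / M
    )
    w = _snp_weights(0.5 * (scores.ell1 + scores.ell2), config.weights)
    res = minimize_scalar(
        _rho_objective,
        bounds=config.rho_bounds,
        args=(z1, z2, v1, v2, cov_unit, w),
        method="bounded",
        options={"xatol": config.optimizer_tol},
    )
    if not res.success or not np.isfinite(res.fun):
        raise RuntimeError("correlation likelihood could not be maximized inside bounds")
    loglik = -0.5 * (res.fun + 2.0 * float(np.sum(w)) * _LOG_2PI)
    return float(res.x), loglik


def _point_estimates(
    stats1: SummaryStats,
    stats2: SummaryStats,
    scores: LDScores,
    M: int,
    config: LikelihoodConfig,
) -> tuple[float, float, float, float, bool]:
    h1, ll1 = fit_heritability(stats1, scores.ell1, M, config)
    h2, ll2 = fit_heritability(stats2, scores.ell2, M, config)
    if h1 < _H_EPS or h2 < _H_EPS:
        # correlation undefined when a heritability hits zero
        return h1, h2, 0.0, ll1 + ll2, False
    rho, llr = fit_correlation(stats1, stats2, scores, h1, h2, M, config)
    return h1, h2, rho, llr, True


def jackknife_se(
    stats1: SummaryStats,
    stats2: SummaryStats,
    scores: LDScores,
    M: int,
    config: LikelihoodConfig = LikelihoodConfig(),
) -> tuple[float, float, float]:
    """Delete-one-block jackknife SEs for (h1^2, h2^2, rho).

    SNPs are partitioned into ``config.jackknife_blocks`` contiguous blocks;
    M in the variance model stays at the full analysis count because deleting
    a block removes observations, not causal SNPs from the polygenic budget.
    """
    m_obs = stats1.n_snps
    b = config.jackknife_blocks
    blocks = np.array_split(np.arange(m_obs), b)
    if min(len(blk) for blk in blocks) < 2:
        raise ValueError("each jackknife block needs at least 2 SNPs")
    theta = np.empty((b, 3))
    for j, blk in enumerate(blocks):
        keep = np.ones(m_obs, dtype=bool)
        keep[blk] = False
        idx = np.flatnonzero(keep)
        h1, h2, rho, _, _ = _point_estimates(
            stats1.select(idx), stats2.select(idx), scores.select(idx), M, config
        )
        theta[j] = (h1, h2, rho)
    dev = theta - theta.mean(axis=0)
    se = np.sqrt((b - 1.0) / b * np.sum(dev * dev, axis=0))
    return float(se[0]), float(se[1]), float(se[2])


def full_fit(
    stats1: SummaryStats,
    stats2: SummaryStats,
    scores: LDScores,
    M: int | None = None,
    config: LikelihoodConfig = LikelihoodConfig(),
) -> FitResult:
    """Two-stage fit (h1^2, h2^2, then rho) plus block-jackknife SEs."""
    if M is None:
        M = stats1.n_snps
    h1, h2, rho, loglik, rho_defined = _point_estimates(stats1, stats2, scores, M, config)
    se_h1, se_h2, se_rho = jackknife_se(stats1, stats2, scores, M, config)
    return FitResult(
        h1_sq_hat=h1,
        h2_sq_hat=h2,
        rho_hat=rho,
        se_h1=se_h1,
        se_h2=se_h2,
        se_rho=se_rho,
        mode=config.mode,
        loglik=loglik,
        converged=True,
        n_snps_used=stats1.n_snps,
        rho_defined=rho_defined,
    )
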