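"""Correlated polygenic architectures and additive phenotypes.

Per-SNP effect sizes for the two populations are drawn from a bivariate
spike-and-slab prior: with probability ``p_causal`` the pair
(beta1_i, beta2_i) is bivariate normal with per-population variance
h^2/(p M) and correlation ``rho_ge``; otherwise both are exactly zero.
The 1/p factor keeps the total expected genetic variance at h^2
regardless of the causal fraction.

Two effect-scale conventions are supported:

``standardized``
    beta applies to variance-standardized genotypes, so each causal SNP
    explains the same expected variance and heritability is exact by
    construction.
``per_allele``
    beta is a per-allele effect; its contribution to trait variance is
    weighted by the allelic impact sigma = sqrt(2 f (1-f)).  Slab variance
    is h^2/(p * sum sigma^2) per population so realized heritability still
    targets h^2.

The realized genetic-impact correlation Cor(sigma1*beta1, sigma2*beta2)
and genetic-effect correlation (per-allele scale) are computed from the
draws, since frequency divergence makes them differ slightly from the
prior parameter rho_ge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgen import GenotypeDataset

__all__ = [
    "ArchitectureParams",
    "EffectSizes",
    "ImpactWeights",
    "PhenotypeSet",
    "draw_effects",
    "impact_weights",
    "realized_impact_correlation",
    "realized_effect_correlation",
    "normalize_genotypes",
    "simulate_phenotypes",
]


@dataclass(frozen=True)
class ArchitectureParams:
    """Parameters of the bivariate spike-and-slab effect model."""

    h1_sq: float
    h2_sq: float
    rho_ge: float
    p_causal: float = 0.99
    M: int = 1000
    effect_scale: str = "standardized"

    def __post_init__(self) -> None:
        for h in (self.h1_sq, self.h2_sq):
            if not (0.0 <= h <= 1.0):
                raise ValueError(f"heritability must be in [0, 1], got {h}")
        if abs(self.rho_ge) > 1.0:
            raise ValueError(f"|rho_ge| must be <= 1, got {self.rho_ge}")
        if not (0.0 < self.p_causal <= 1.0):
            raise ValueError("p_causal must be in (0, 1]")
        if self.M < 1:
            raise ValueError("M must be positive")
        if self.effect_scale not in ("standardized", "per_allele"):
            raise ValueError("effect_scale must be 'standardized' or 'per_allele'")


@dataclass
class EffectSizes:
    beta1: np.ndarray
    beta2: np.ndarray
    causal_mask: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.causal_mask = np.asarray(self.causal_mask, dtype=bool)
        if not (self.beta1.shape == self.beta2.shape == self.causal_mask.shape):
            raise ValueError("effect vectors and causal mask must share a shape")
        if np.any(self.beta1[~self.causal_mask] != 0.0) or np.any(
            self.beta2[~self.causal_mask] != 0.0
        ):
            raise ValueError("non-causal SNPs must have exactly zero effects")


@dataclass
class ImpactWeights:
    """Allelic impacts sigma_k = sqrt(2 f_k (1 - f_k)) for both populations."""

    sigma1: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.sigma1 = np.asarray(self.sigma1, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        for s in (self.sigma1, self.sigma2):
            if np.any((s <= 0.0) | (s > np.sqrt(0.5) + 1e-12)):
                raise ValueError("sigma must lie in (0, sqrt(1/2)]")


@dataclass
class PhenotypeSet:
    values: np.ndarray
    h_sq_used: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotypes must be finite")


def draw_effects(
    params: ArchitectureParams,
    seed: int | np.random.Generator,
    weights: ImpactWeights | None = None,
) -> EffectSizes:
    """Draw spike-and-slab effect pairs for M SNPs.

    In ``per_allele`` mode the slab variances depend on the allelic impacts,
    so ``weights`` is required there.
    """
    rng = np.random.default_rng(seed)
    m, p = params.M, params.p_causal
    causal = rng.random(m) < p
    if params.effect_scale == "standardized":
        var1 = np.full(m, params.h1_sq / (p * m))
        var2 = np.full(m, params.h2_sq / (p * m))
    else:
        if weights is None:
            raise ValueError("per_allele mode requires impact weights")
        if weights.sigma1.size != m:
            raise ValueError("impact weights length must equal M")
        var1 = np.full(m, params.h1_sq / (p * np.sum(weights.sigma1**2)))
        var2 = np.full(m, params.h2_sq / (p * np.sum(weights.sigma2**2)))
    s1, s2 = np.sqrt(var1), np.sqrt(var2)
    z1 = rng.standard_normal(m)
    z2 = rng.standard_normal(m)
    rho = params.rho_ge
    beta1 = s1 * z1
    beta2 = s2 * (rho * z1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * z2)
    beta1[~causal] = 0.0
    beta2[~causal] = 0.0
    return EffectSizes(beta1=beta1, beta2=beta2, causal_mask=causal, scale=params.effect_scale)


def impact_weights(f1: np.ndarray, f2: np.ndarray) -> ImpactWeights:
    """sigma_k = sqrt(2 f_k (1 - f_k)) elementwise; errors on fixed alleles."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    for f in (f1, f2):
        if np.any((f <= 0.0) | (f >= 1.0)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
    return ImpactWeights(
        sigma1=np.sqrt(2.0 * f1 * (1.0 - f1)),
        sigma2=np.sqrt(2.0 * f2 * (1.0 - f2)),
    )


def _checked_correlation(a: np.ndarray, b: np.ndarray) -> float:
    nonzero = (a != 0.0) & (b != 0.0)
    if np.count_nonzero(nonzero) < 2:
        raise ValueError("correlation undefined: fewer than 2 nonzero effect pairs")
    return float(np.corrcoef(a, b)[0, 1])


def realized_impact_correlation(effects: EffectSizes, weights: ImpactWeights) -> float:
    """Realized genetic-impact correlation Cor(sigma1*beta1, sigma2*beta2).

    beta in this formula is the per-allele effect; effects drawn on the
    standardized scale are already impact-scale (sigma * per-allele), so
    the weighting applies only to per-allele draws.
    """
    if effects.scale == "per_allele":
        a = weights.sigma1 * effects.beta1
        b = weights.sigma2 * effects.beta2
    else:
        a, b = effects.beta1, effects.beta2
    return _checked_correlation(a, b)


def realized_effect_correlation(effects: EffectSizes, weights: ImpactWeights) -> float:
    """Realized genetic-effect correlation: correlation of per-allele effects."""
    if effects.scale == "per_allele":
        a, b = effects.beta1, effects.beta2
    else:
        a = effects.beta1 / weights.sigma1
        b = effects.beta2 / weights.sigma2
    return _checked_correlation(a, b)


def normalize_genotypes(data: GenotypeDataset, dtype=np.float64) -> np.ndarray:
    """Variance-standardize dosages: (x - 2f) / sqrt(2 f (1-f)), column-wise.

    Uses the sample allele frequencies, so every output column has exactly
    zero mean (to floating tolerance); the variance is ~1 under
    Hardy-Weinberg proportions.  ``dtype=np.float32`` halves memory for
    large cohorts at the cost of ~1e-7 relative rounding.
    """
    f = data.freqs
    if np.any((f <= 0.0) | (f >= 1.0)):
        raise ValueError("cannot standardize monomorphic SNP columns")
    x = data.dosages.astype(dtype)
    x -= (2.0 * f).astype(dtype)
    x /= np.sqrt(2.0 * f * (1.0 - f)).astype(dtype)
    return x


def simulate_phenotypes(
    X: np.ndarray,
    beta: np.ndarray,
    h_sq: float,
    seed: int | np.random.Generator,
    scale: str = "standardized",
    sigma: np.ndarray | None = None,
) -> PhenotypeSet:
    """Additive phenotypes Y = X gamma + eps with Var(eps) = 1 - h^2.

    ``X`` is the standardized dosage matrix; ``gamma`` is the
    standardized-scale effect (beta itself, or sigma*beta when the effects
    were drawn per-allele, which already carries expected variance h^2).
    """
    if not (0.0 <= h_sq <= 1.0):
        raise ValueError("h_sq must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if scale == "per_allele":
        if sigma is None:
            raise ValueError("per_allele phenotypes require the sigma vector")
        gamma = sigma * beta
    else:
        gamma = beta
    g = X @ gamma.astype(X.dtype)
    eps = rng.normal(0.0, np.sqrt(1.0 - h_sq), size=X.shape[0])
    return PhenotypeSet(values=np.asarray(g, dtype=float) + eps, h_sq_used=h_sq)


def export_effects_table(effects: EffectSizes, weights: ImpactWeights, snp_ids, path) -> None:
    """Per-SNP truth table: snp_id, beta1, beta2, causal, sigma1, sigma2 (TSV)."""
    import pandas as pd

    pd.DataFrame(
        {
            "snp_id": np.asarray(snp_ids),
            "beta1": effects.beta1,
            "beta2": effects.beta2,
            "causal": effects.causal_mask.astype(int),
            "sigma1": weights.sigma1,
            "sigma2": weights.sigma2,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
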