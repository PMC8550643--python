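"""Spike-and-slab effects, phenotypes and the chi-square/LD-score identity.

Draws correlated effect sizes for two populations, simulates one cohort's
phenotype at h^2 = 0.5, runs the marginal GWAS, and checks the model
identity E[z^2] = 1 + N h^2 mean(ell) / M against LD scores from a
500-individual reference panel.
"""

import numpy as np

from transcorr import (
    ArchitectureParams,
    PopulationModel,
    compute_ld_scores,
    draw_effects,
    impact_weights,
    normalize_genotypes,
    realized_impact_correlation,
    run_gwas,
    simulate_genotypes,
    simulate_phenotypes,
)

M, N, H2 = 2000, 4000, 0.5
rng = np.random.default_rng(0)
freqs = rng.uniform(0.05, 0.95, M)
model = PopulationModel(fst=0.11, ld_rho=0.9)
cohort = simulate_genotypes(freqs, model, N, seed=1)
panel = simulate_genotypes(freqs, model, 500, seed=2)

params = ArchitectureParams(h1_sq=H2, h2_sq=H2, rho_ge=0.5, p_causal=0.99, M=M)
effects = draw_effects(params, seed=3)
weights = impact_weights(cohort.freqs, cohort.freqs)
print(f"causal fraction: {effects.causal_mask.mean():.3f} (target p=0.99)")
print(f"realized impact correlation of the draw: "
      f"{realized_impact_correlation(effects, weights):.3f} (target rho_ge=0.5)")

x = normalize_genotypes(cohort)
phen = simulate_phenotypes(x, effects.beta1, H2, seed=4)
print(f"phenotype variance: {phen.values.var():.3f} (model: 1.0)")

stats = run_gwas(cohort, phen, standardized=x)
scores = compute_ld_scores(panel, panel, W=100)
observed = np.mean(stats.z**2)
predicted = 1.0 + N * H2 * np.mean(scores.ell1) / M
print(f"mean chi-square: observed {observed:.2f}, "
      f"LD-score identity predicts {predicted:.2f}")
# agreement indicates the GWAS, the architecture and the reference-panel
# LD scores are on one consistent scale -- the premise of the estimator
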