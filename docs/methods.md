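# Methods

## Scope and intent

`transcorr` is a self-contained simulation laboratory for summary-statistics
estimation of trans-ancestral genetic correlation. Every stage of a real
cross-population analysis has a synthetic stand-in whose statistical
properties are controlled and seeded: allele-frequency divergence, linkage
disequilibrium (LD), polygenic architectures correlated between populations,
marginal GWAS, reference-panel LD scores, and the likelihood fit itself.
The package does not read real haplotype resources; its simulator is built
to reproduce the two properties the evaluation depends on — frequency
divergence between populations and distance-decaying LD within them — not
the fine structure of any particular genome.

## Genotype simulation

**Frequency divergence.** Ancestral allele frequencies are uniform on
[0.05, 0.95]. Each population drifts under the Balding–Nichols model:
population frequency ~ Beta(f(1−F)/F, (1−f)(1−F)/F) with drift parameter
F = Fst, mean f and variance F·f(1−f), clipped to [0.001, 0.999] to avoid
degenerate thresholds. Preset models use Fst 0.11 with latent LD
autocorrelation 0.9 for EUR/EAS-like populations and Fst 0.17 with 0.8 for
YRI-like (shorter-range LD); the ordering matches known relative divergence
and LD extent, the exact values are tunable configuration, not claims.

**LD.** Each haplotype is a latent stationary Gaussian AR(1) process across
SNP indices (autocorrelation `ld_rho`), thresholded per SNP at the normal
quantile of its target frequency; a genotype is the sum of two independent
haplotypes. Haplotypic correlation therefore decays geometrically with
index distance (the binary correlation at lag k follows from the
bivariate-normal orthant probability at latent correlation `ld_rho`^k, the
oracle used in the tests). There is no physical map: positions are 0-based
SNP indices and "distance" is index difference.

**Admixture.** An admixed cohort is built from two source haplotype pools.
Each individual draws a personal ancestry proportion θ ~ Beta(νp, ν(1−p))
with mean p = `admix_prop` (default 0.8) and concentration ν = 10 — giving
a spread of global ancestry (SD ≈ 0.12) like that of African-American
cohorts — and each `block_len`-SNP block of each haplotype then comes from
source a with probability θ. Between-individual variation in θ is what
creates long-range LD between blocks: for SNPs i, j in different blocks the
genotype covariance is 4·Var(θ)·δᵢδⱼ, with δ the source frequency
difference (verified against this closed form in the tests). With a fixed
proportion (ν → ∞) ancestry blocks are independent and only the strong
within-block mosaic LD remains; the package exposes that degenerate variant
(`prop_concentration=None`) but does not default to it, because it removes
the phenomenon the admixture experiment studies.

**QC.** Cohorts are filtered to minor allele frequency ≥ f0 (default 0.01)
and intersected on SNPs polymorphic in both populations (population 1's
order). A kinship filter (half the correlation of per-SNP-standardized
genotype vectors, greedy removal of the higher index of each violating
pair above r0 = 0.05) is implemented and tested, but scenarios leave it off
by default: simulated individuals are exchangeably independent, so at
cohort scale the filter is an O(N²M) no-op. Reference panels are L
individuals (default 500) sampled without replacement from an
independently simulated pool of the assigned source population.

## Effect sizes and phenotypes

Per-SNP effect pairs follow the bivariate spike-and-slab prior with slab
probability p (default 0.99), correlation ρ_ge and per-population slab
variance h²/(pM); the 1/p factor keeps the total expected genetic variance
at h² for any causal fraction. Phenotypes are Y = Xγ + ε on standardized
genotypes X, with ε ~ N(0, 1−h²), so trait variance is 1 and heritability
is exact by construction.

Two effect-scale conventions are supported, because the generative
equations in this literature mix them: `standardized` (the default)
draws effects that multiply variance-standardized genotypes directly, while
`per_allele` draws per-allele effects whose slab variance is
h²/(p·Σσ²) with σ = √(2f(1−f)), so realized heritability still targets h²
despite frequency-dependent impact. The realized genetic-impact correlation
Cor(σ₁β₁, σ₂β₂) is computed on the impact scale: per-allele draws are
multiplied by σ, standardized draws already are impact-scale. (Applying the
σ-weighting twice to standardized draws would attenuate the value ~4%
below ρ_ge at Fst 0.11 for no modeling reason.) The genetic-effect
correlation is the correlation of the per-allele effects.

## GWAS and LD scores

Association is simple linear regression of the phenotype on each
standardized dosage column: beta = r·sd(Y), se = √((1−r²)/(n−2))·sd(Y),
z = beta/se, with |z| capped at √(n−2) for degenerate perfect fits. Under
the generative model mean(z²) = 1 + N h² mean(ℓ)/M, the identity used as
the central internal consistency check between the GWAS, the architecture
and the scores.

Within-population LD scores sum bias-corrected squared panel correlations
over a ±W SNP window (W default 100, which captures >99% of the AR(1) LD
mass at `ld_rho` ≤ 0.95): ℓᵢ = Σⱼ r̂²(i,j) − (1−r̂²(i,j))/(L−2), self term
included (= 1). Cross-population scores sum the product of the two panels'
correlations; the small-sample correction is omitted there because the
panels are independent samples, making E[r̂₁r̂₂] = r₁r₂ unbiased. Effect-mode
cross scores weight each summand by σ₁ⱼσ₂ⱼ/(c₁c₂) with c_k the
root-mean-square impact over the analysis SNPs, which maps the per-allele
effect covariance onto the same h²/M parameterization — a derivation
validated by parameter recovery, not taken from any published score
formula. SNPs monomorphic inside a panel draw contribute zero correlation
with a warning rather than aborting.

## Estimation

The fit is two-stage: each heritability maximizes the weighted sum of
per-SNP normal log-likelihoods of z with variance 1 + N h² ℓ/M over
h² ∈ [0,1]; the correlation then maximizes the per-SNP bivariate-normal
log-likelihood over ρ ∈ [−1,1] with the heritabilities held fixed and
off-diagonal √(N₁N₂) ρ √(h₁²h₂²) ℓₓ/M (mode selecting the ℓₓ column).
Weights are 1/max(ℓ, 1) per SNP (mean of the two populations' scores in
the correlation stage), down-weighting signal double-counted through LD.
Optimization is bounded scalar search with tolerance 1e-6; it agrees with
a 2,001-point dense grid to 0.002 and, in the no-LD limit, with the
closed-form moment estimators ĥ² = M(mean z²−1)/N and
ρ̂ = M·mean(z₁z₂)/(√(N₁N₂)·√(ĥ₁²ĥ₂²)) to 0.02. Any candidate ρ whose
2×2 covariance is not positive definite at some SNP is rejected inside the
bounded search. If a heritability estimate hits zero, ρ is undefined; the
fit reports ρ = 0 with `rho_defined=False`.

Standard errors come from a delete-one-block jackknife over b contiguous
SNP blocks (default 20; block length far exceeds the LD range), re-running
the full two-stage fit per deletion; M in the variance model stays at the
full analysis count because deleting observations does not shrink the
polygenic budget. At the default scenario the mean jackknife SE is within
a factor 1.5 of the replicate SD for all three parameters (ρ ratio ≈ 0.9).

## Evaluation harness and problem sizes

A scenario bundles population models, cohort sizes, SNP count, panel size,
architecture, QC and a base seed; every replicate derives all stage seeds
from (base_seed, replicate), so reports are bitwise reproducible. The
default scenario — N = 10,000 per cohort, M = 8,000 SNPs, L = 500,
p = 0.99, 30 replicates — is the package's desk-scale stand-in for
chromosome-scale studies (tens of thousands of individuals over 200k+
SNPs); it was chosen so the 'ideal estimate' thresholds are attainable in
minutes on one core while keeping N·h²·ℓ/M, the per-SNP signal strength,
in a realistic regime. Reduced variants (N = 4,000, M = 2,000) are used
for checks that do not depend on the default sizes (null calibration,
boundary behavior, misspecification direction).

Summaries report bias (mean estimate − truth), empirical SE (replicate SD),
mean jackknife SE, and the 'ideal estimate' flag: accurate (|bias| < 0.05)
and stable (SE < 0.1). Sweeps over L, N or M report the smallest value
from which every larger tested value is also ideal, guarding against
one-off Monte Carlo flips. The misspecification experiment runs identical
seeds with a correct versus LD-discordant panel for population 2, so
paired differences isolate the panel effect; population 1's estimates are
bitwise unchanged.

## What the simulator does and does not show

Passing recovery tests here demonstrates that the estimator is consistent
and calibrated when its variance model matches the data-generating LD and
the panels are drawn from the study populations. Real-data complications
deliberately out of scope: physical/recombination maps, MAF-dependent
architectures beyond the two scale conventions, binary traits and the
liability scale, sample overlap, genomic-control rescaling, covariates and
population stratification within cohorts, and sex chromosomes.

Directions of misspecification effects transfer only partly. An
LD-discordant panel for population 2 (shorter-range LD than the cohort)
inflates ĥ₂² strongly and ρ̂ mildly here, matching the direction reported
for real-panel mismatches. For admixed cohorts, however, this simulator
gives *over*-estimated admixed-population heritability (the windowed panel
scores cannot see the long-range admixture LD that inflates the cohort's
chi-squares, and a single-source panel is more biased than a panel from
the admixed population itself), whereas the HapMap-based result this
harness emulates reported underestimation; that discrepancy is tied to the
real haplotype structure and estimator internals the stand-in does not
reproduce, and the admixture tests therefore assert only the robust facts
(source-panel arm more biased, non-admixed population unaffected, pipeline
completes).

## Numerical choices

- Haplotype latents are float32 in SNP-major layout (the AR(1) recurrence
  runs on contiguous rows); cohort standardization uses float64 by default
  in the API and float32 inside the pipeline for memory.
- Frequency clipping at [0.001, 0.999]; uniform ancestral band [0.05,
  0.95] so the post-QC SNP count stays near the configured M.
- All randomness flows through named per-stage children of
  numpy's SeedSequence([base_seed, replicate]); no global RNG state.
- Ties in the bounded likelihood search resolve toward the interior;
  optimizer tolerance 1e-6.
- Degenerate inputs fail loudly (monomorphic columns in GWAS, empty QC
  results, misaligned SNP sets) except panel-monomorphic SNPs in scores,
  which warn and contribute zero.
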