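"""Desk-scale evaluation harness: scenario sweeps, bias/SE summaries.

A :class:`Scenario` bundles everything one simulated study needs: the two
population models (or an admixture spec for population 2), cohort sizes,
SNP count, reference-panel size, the effect-size architecture, QC
thresholds and a base seed.  :func:`run_scenario` executes the full
pipeline per replicate -- simulate genotypes, QC, draw effects, simulate
phenotypes, run the GWAS, compute LD scores from seeded reference panels,
fit the weighted likelihood -- with all randomness derived from
(base_seed, replicate), so reports are bitwise reproducible.

Estimates are summarized with the 'ideal estimate' rule: a parameter is
ideal when |mean estimate - truth| < 0.05 (accurate) and the empirical SD
across replicates is < 0.1 (stable).  Sweeps over L, N or M report the
smallest value from which every tested value onward is ideal.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .architecture import (
    ArchitectureParams,
    draw_effects,
    impact_weights,
    normalize_genotypes,
    realized_effect_correlation,
    realized_impact_correlation,
    simulate_phenotypes,
)
from .estimator import FitResult, LikelihoodConfig, full_fit
from .ldscores import compute_ld_scores
from .popgen import (
    GenotypeDataset,
    PopulationModel,
    QCThresholds,
    draw_ancestral_frequencies,
    draw_population_frequencies,
    filter_maf,
    filter_related,
    intersect_snps,
    sample_reference_panel,
    simulate_admixed,
    simulate_genotypes,
)
from .sumstats import run_gwas

__all__ = [
    "AdmixtureSpec",
    "Scenario",
    "EvalReport",
    "default_scenario",
    "default_parameter_grid",
    "run_scenario",
    "summarize",
    "sweep",
    "mismatch_experiment",
    "admixture_experiment",
    "scenario_from_yaml",
]

ACCURACY_LIMIT = 0.05  # 'accurate': |bias| below this
STABILITY_LIMIT = 0.1  # 'stable': empirical SE below this

# population presets; drift/LD values are tunable configuration whose ordering
# matches the relative divergence and LD extent of the continental panels
EUR_LIKE = PopulationModel(fst=0.11, ld_rho=0.9, label="EUR-like")
EAS_LIKE = PopulationModel(fst=0.11, ld_rho=0.9, label="EAS-like")
YRI_LIKE = PopulationModel(fst=0.17, ld_rho=0.8, label="YRI-like")


@dataclass(frozen=True)
class AdmixtureSpec:
    """Two-way admixture for population 2 (African-American-like defaults)."""

    source_a: PopulationModel = YRI_LIKE
    source_b: PopulationModel = EUR_LIKE
    prop: float = 0.8
    block_len: int = 50
    prop_concentration: float | None = 10.0


@dataclass(frozen=True)
class Scenario:
    """One simulated study design; see module docstring."""

    pop1: PopulationModel
    pop2: PopulationModel
    N1: int
    N2: int
    M: int
    L: int
    arch: ArchitectureParams
    qc: QCThresholds = QCThresholds()
    admixture: AdmixtureSpec | None = None
    panel1_source: str | PopulationModel = "self"
    panel2_source: str | PopulationModel = "self"
    n_replicates: int = 30
    base_seed: int = 0
    window: int = 100
    apply_kinship_filter: bool = False
    likelihood: LikelihoodConfig = field(default_factory=LikelihoodConfig)

    def __post_init__(self) -> None:
        for name in ("N1", "N2", "M", "L", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def default_scenario(**overrides) -> Scenario:
    """The package's default desk-scale study conditions.

    Two EUR/EAS-like populations, N1 = N2 = 10,000, M = 8,000 SNPs,
    L = 500 reference individuals, spike-and-slab with p = 0.99 and
    h1^2 = h2^2 = rho_ge = 0.5, 30 replicates.
    """
    arch = overrides.pop(
        "arch",
        ArchitectureParams(h1_sq=0.5, h2_sq=0.5, rho_ge=0.5, p_causal=0.99, M=8000),
    )
    base = dict(
        pop1=EUR_LIKE,
        pop2=replace(EAS_LIKE, label="pop2"),
        N1=10_000,
        N2=10_000,
        M=8_000,
        L=500,
        arch=arch,
    )
    base.update(overrides)
    return Scenario(**base)


# --------------------------------------------------------------------------
# single-replicate pipeline


def _panel_pool_seeded(
    source,
    scenario: Scenario,
    which: int,
    ancestral,
    own_freqs: np.ndarray,
    own_model: PopulationModel,
    hap_pools,
    seed_freq,
    seed_geno,
) -> GenotypeDataset:
    """Simulate the L-individual pool the reference panel is sampled from."""
    L = scenario.L
    if isinstance(source, PopulationModel):
        freqs = draw_population_frequencies(ancestral, source, seed_freq)
        return simulate_genotypes(freqs, source, L, seed_geno)
    if source == "self":
        if which == 2 and scenario.admixture is not None:
            adm = scenario.admixture
            return simulate_admixed(
                hap_pools[0], hap_pools[1], adm.prop, adm.block_len, L, seed_geno,
                prop_concentration=adm.prop_concentration,
            )
        return simulate_genotypes(own_freqs, own_model, L, seed_geno)
    if source in ("source_a", "source_b"):
        if scenario.admixture is None:
            raise ValueError("source_a/source_b panels require an admixture scenario")
        pool = hap_pools[0] if source == "source_a" else hap_pools[1]
        return sample_reference_panel(pool, L, seed_geno)
    raise ValueError(f"unknown panel source {source!r}")


def _subset_to_ids(data: GenotypeDataset, ids: np.ndarray) -> GenotypeDataset:
    pos = {sid: i for i, sid in enumerate(data.snp_ids)}
    return data.select_snps(np.array([pos[s] for s in ids]))


@dataclass
class ReplicateArtifacts:
    """Everything one pipeline replicate produced, for export or inspection."""

    fit: FitResult
    truth: dict
    stats1: object
    stats2: object
    scores: object
    panel1: GenotypeDataset
    panel2: GenotypeDataset


def run_replicate(scenario: Scenario, replicate: int, return_artifacts: bool = False):
    """Run the full simulate->QC->GWAS->scores->fit pipeline once.

    Returns ``(fit, truth)`` — the fit and a truth record carrying the
    target parameters and the realized effect/impact correlations of the
    drawn architecture — or a :class:`ReplicateArtifacts` when
    ``return_artifacts`` is set.
    """
    ss = np.random.SeedSequence([int(scenario.base_seed), int(replicate)])
    seeds = ss.spawn(16)
    adm = scenario.admixture

    ancestral = draw_ancestral_frequencies(scenario.M, seeds[0])
    f1 = draw_population_frequencies(ancestral, scenario.pop1, seeds[1])
    cohort1 = simulate_genotypes(f1, scenario.pop1, scenario.N1, seeds[3])

    hap_pools: tuple[GenotypeDataset, GenotypeDataset] | None = None
    if adm is not None:
        fa = draw_population_frequencies(ancestral, adm.source_a, seeds[2])
        fb = draw_population_frequencies(ancestral, adm.source_b, seeds[4])
        pool_n = max(scenario.N2, scenario.L)
        pool_a = simulate_genotypes(fa, adm.source_a, pool_n, seeds[5], keep_haplotypes=True)
        pool_b = simulate_genotypes(fb, adm.source_b, pool_n, seeds[6], keep_haplotypes=True)
        hap_pools = (pool_a, pool_b)
        cohort2 = simulate_admixed(
            pool_a, pool_b, adm.prop, adm.block_len, scenario.N2, seeds[7],
            prop_concentration=adm.prop_concentration,
        )
        f2 = cohort2.freqs
    else:
        f2 = draw_population_frequencies(ancestral, scenario.pop2, seeds[2])
        cohort2 = simulate_genotypes(f2, scenario.pop2, scenario.N2, seeds[7])

    pool1 = _panel_pool_seeded(
        scenario.panel1_source, scenario, 1, ancestral, f1, scenario.pop1,
        hap_pools, seeds[8], seeds[9],
    )
    pool2 = _panel_pool_seeded(
        scenario.panel2_source, scenario, 2, ancestral, f2, scenario.pop2,
        hap_pools, seeds[10], seeds[11],
    )
    panel1 = sample_reference_panel(pool1, scenario.L, seeds[14])
    panel2 = sample_reference_panel(pool2, scenario.L, seeds[15])

    cohort1 = filter_maf(cohort1, scenario.qc.f0)
    cohort2 = filter_maf(cohort2, scenario.qc.f0)
    if scenario.apply_kinship_filter:
        cohort1 = filter_related(cohort1, scenario.qc.r0)
        cohort2 = filter_related(cohort2, scenario.qc.r0)
    cohort1, cohort2 = intersect_snps(cohort1, cohort2)
    panel1 = _subset_to_ids(panel1, cohort1.snp_ids)
    panel2 = _subset_to_ids(panel2, cohort2.snp_ids)

    m = cohort1.n_snps
    arch = replace(scenario.arch, M=m)
    weights = impact_weights(cohort1.freqs, cohort2.freqs)
    effects = draw_effects(arch, seeds[12], weights=weights)

    phen_seeds = seeds[13].spawn(2)
    x1 = normalize_genotypes(cohort1, dtype=np.float32)
    phen1 = simulate_phenotypes(
        x1, effects.beta1, arch.h1_sq, phen_seeds[0], scale=arch.effect_scale,
        sigma=weights.sigma1,
    )
    stats1 = run_gwas(cohort1, phen1, standardized=x1)
    del x1
    x2 = normalize_genotypes(cohort2, dtype=np.float32)
    phen2 = simulate_phenotypes(
        x2, effects.beta2, arch.h2_sq, phen_seeds[1], scale=arch.effect_scale,
        sigma=weights.sigma2,
    )
    stats2 = run_gwas(cohort2, phen2, standardized=x2)
    del x2

    scores = compute_ld_scores(panel1, panel2, W=scenario.window)
    fit = full_fit(stats1, stats2, scores, M=m, config=scenario.likelihood)
    truth = {
        "h1_sq": arch.h1_sq,
        "h2_sq": arch.h2_sq,
        "rho_ge": arch.rho_ge,
        "rho_gi": realized_impact_correlation(effects, weights),
        "rho_effect": realized_effect_correlation(effects, weights),
        "n_snps": m,
    }
    if return_artifacts:
        return ReplicateArtifacts(
            fit=fit, truth=truth, stats1=stats1, stats2=stats2, scores=scores,
            panel1=panel1, panel2=panel2,
        )
    return fit, truth


def run_scenario(scenario: Scenario):
    """All replicates of a scenario.

    Returns ``(fits, truth, failures)`` where ``fits`` has one FitResult
    per successful replicate, ``truth`` carries the target parameters and
    the mean realized correlations, and ``failures`` maps replicate index
    to the error message (a stage failure skips the replicate, not the
    scenario).
    """
    fits: list[FitResult] = []
    truths: list[dict] = []
    failures: dict[int, str] = {}
    for r in range(scenario.n_replicates):
        try:
            fit, truth = run_replicate(scenario, r)
        except Exception as exc:  # noqa: BLE001 - recorded, scenario continues
            failures[r] = f"{type(exc).__name__}: {exc}"
            continue
        fits.append(fit)
        truths.append(truth)
    if not truths:
        raise RuntimeError("every replicate failed; first error: " + next(iter(failures.values())))
    truth = {
        "h1_sq": truths[0]["h1_sq"],
        "h2_sq": truths[0]["h2_sq"],
        "rho_ge": truths[0]["rho_ge"],
        "rho_gi_mean": float(np.mean([t["rho_gi"] for t in truths])),
        "rho_effect_mean": float(np.mean([t["rho_effect"] for t in truths])),
        "n_snps_mean": float(np.mean([t["n_snps"] for t in truths])),
    }
    return fits, truth, failures


# --------------------------------------------------------------------------
# summaries

_PARAMS = {
    "rho": ("rho_hat", "se_rho", "rho_ge"),
    "h1_sq": ("h1_sq_hat", "se_h1", "h1_sq"),
    "h2_sq": ("h2_sq_hat", "se_h2", "h2_sq"),
}


@dataclass
class EvalReport:
    """Bias / SE / 'ideal estimate' summary of one scenario's replicates."""

    truth: dict
    estimates: dict
    bias: dict
    empirical_se: dict
    mean_reported_se: dict
    ideal: dict
    n_replicates: int
    n_failures: int = 0
    se_defined: bool = True

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def summarize(fits: list[FitResult], truth: dict, n_failures: int = 0) -> EvalReport:
    """Bias, empirical SE across replicates, and the ideal classification."""
    if not fits:
        raise ValueError("no successful replicates to summarize")
    se_defined = len(fits) >= 2
    estimates, bias, emp_se, rep_se, ideal = {}, {}, {}, {}, {}
    for name, (est_attr, se_attr, truth_key) in _PARAMS.items():
        vals = np.array([getattr(f, est_attr) for f in fits])
        estimates[name] = vals.tolist()
        bias[name] = float(vals.mean() - truth[truth_key])
        emp_se[name] = float(vals.std(ddof=1)) if se_defined else float("nan")
        rep_se[name] = float(np.mean([getattr(f, se_attr) for f in fits]))
        ideal[name] = bool(
            se_defined
            and abs(bias[name]) < ACCURACY_LIMIT
            and emp_se[name] < STABILITY_LIMIT
        )
    return EvalReport(
        truth=truth,
        estimates=estimates,
        bias=bias,
        empirical_se=emp_se,
        mean_reported_se=rep_se,
        ideal=ideal,
        n_replicates=len(fits),
        n_failures=n_failures,
        se_defined=se_defined,
    )


def default_parameter_grid(template: Scenario) -> list[Scenario]:
    """The reproduction-style grid of true parameter values.

    Varies the genetic correlation from -1 to 1 and each heritability from
    0 to 1, all in increments of 0.1, holding the other two parameters at
    0.5.  Returns one scenario per grid point.
    """
    scenarios = []
    for rho in np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 1):
        scenarios.append(
            replace(template, arch=replace(template.arch, rho_ge=float(rho)))
        )
    for h in np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 1):
        scenarios.append(
            replace(template, arch=replace(template.arch, h1_sq=float(h)))
        )
        scenarios.append(
            replace(template, arch=replace(template.arch, h2_sq=float(h)))
        )
    return scenarios


def _scenario_with(template: Scenario, axis: str, value: int) -> Scenario:
    if axis == "L":
        return replace(template, L=value)
    if axis == "N":
        return replace(template, N1=value, N2=value)
    if axis == "M":
        return replace(template, M=value)
    raise ValueError("axis must be one of 'L', 'N', 'M'")


def sweep(axis: str, values: list[int], template: Scenario):
    """Run the scenario along one axis; find the smallest adequate value.

    The reported minimum per parameter is the first value from which every
    larger tested value is also ideal, guarding against one-off Monte Carlo
    flips; ``None`` when no such value exists.
    """
    if not values:
        raise ValueError("sweep needs at least one axis value")
    if list(values) != sorted(values):
        raise ValueError("sweep values must be sorted ascending")
    reports = {}
    for v in values:
        fits, truth, failures = run_scenario(_scenario_with(template, axis, v))
        reports[v] = summarize(fits, truth, n_failures=len(failures))
    minima = {
        name: _first_stably_ideal([reports[v].ideal[name] for v in values], values)
        for name in _PARAMS
    }
    return reports, minima


def _first_stably_ideal(flags: list[bool], values: list[int]):
    """Smallest value that is ideal along with every larger tested value."""
    for i in range(len(values)):
        if all(flags[i:]):
            return values[i]
    return None


def mismatch_experiment(template: Scenario, wrong_panel_source: PopulationModel):
    """Correct vs deliberately mismatched reference panel for population 2.

    Both arms run the identical replicates (same seeds); only population
    2's panel source differs, so per-replicate differences isolate the
    panel-misspecification effect.
    """
    if wrong_panel_source == template.pop2:
        raise ValueError("wrong panel source must differ from population 2's model")
    correct = replace(template, panel2_source="self")
    wrong = replace(template, panel2_source=wrong_panel_source)
    fits_c, truth_c, fail_c = run_scenario(correct)
    fits_w, truth_w, fail_w = run_scenario(wrong)
    return (
        summarize(fits_c, truth_c, n_failures=len(fail_c)),
        summarize(fits_w, truth_w, n_failures=len(fail_w)),
    )


def admixture_experiment(template: Scenario):
    """Own-panel vs single-source-panel arms for an admixed population 2."""
    if template.admixture is None:
        raise ValueError("template must define an admixture spec for population 2")
    own = replace(template, panel2_source="self")
    source = replace(template, panel2_source="source_a")
    fits_a, truth_a, fail_a = run_scenario(own)
    fits_b, truth_b, fail_b = run_scenario(source)
    return (
        summarize(fits_a, truth_a, n_failures=len(fail_a)),
        summarize(fits_b, truth_b, n_failures=len(fail_b)),
    )


# --------------------------------------------------------------------------
# report and config I/O


def replicates_to_csv(fits: list[FitResult], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["replicate", "h1_sq_hat", "h2_sq_hat", "rho_hat", "se_h1", "se_h2", "se_rho"]
        )
        for i, f in enumerate(fits):
            writer.writerow(
                [i, f.h1_sq_hat, f.h2_sq_hat, f.rho_hat, f.se_h1, f.se_h2, f.se_rho]
            )


def scenario_from_yaml(path) -> Scenario:
    """Build a Scenario from a YAML config.

    Schema (all blocks optional; missing keys fall back to the defaults of
    :func:`default_scenario`)::

        populations:
          pop1: {fst: 0.11, ld_rho: 0.9}
          pop2: {fst: 0.11, ld_rho: 0.9}
        admixture: {prop: 0.8, block_len: 50,
                    source_a: {fst: 0.17, ld_rho: 0.8},
                    source_b: {fst: 0.11, ld_rho: 0.9}}
        cohort: {N1: 10000, N2: 10000}
        snps: {M: 8000}
        panel: {L: 500, window: 100}
        qc: {f0: 0.01, r0: 0.05, apply_kinship_filter: false}
        arch: {h1_sq: 0.5, h2_sq: 0.5, rho_ge: 0.5, p_causal: 0.99,
               effect_scale: standardized}
        replicates: 30
        seed: 0
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    over: dict = {}
    pops = cfg.get("populations", {})
    for key, name in (("pop1", "pop1"), ("pop2", "pop2")):
        if key in pops:
            spec = pops[key]
            over[name] = PopulationModel(
                fst=float(spec["fst"]), ld_rho=float(spec["ld_rho"]), label=key
            )
    if "admixture" in cfg:
        a = cfg["admixture"]
        kwargs = {}
        for src in ("source_a", "source_b"):
            if src in a:
                kwargs[src] = PopulationModel(
                    fst=float(a[src]["fst"]), ld_rho=float(a[src]["ld_rho"]), label=src
                )
        if "prop" in a:
            kwargs["prop"] = float(a["prop"])
        if "block_len" in a:
            kwargs["block_len"] = int(a["block_len"])
        over["admixture"] = AdmixtureSpec(**kwargs)
    cohort = cfg.get("cohort", {})
    for k in ("N1", "N2"):
        if k in cohort:
            over[k] = int(cohort[k])
    if "M" in cfg.get("snps", {}):
        over["M"] = int(cfg["snps"]["M"])
    panel = cfg.get("panel", {})
    if "L" in panel:
        over["L"] = int(panel["L"])
    if "window" in panel:
        over["window"] = int(panel["window"])
    qc = cfg.get("qc", {})
    if qc:
        over["qc"] = QCThresholds(
            f0=float(qc.get("f0", 0.01)), r0=float(qc.get("r0", 0.05))
        )
        if "apply_kinship_filter" in qc:
            over["apply_kinship_filter"] = bool(qc["apply_kinship_filter"])
    arch_cfg = cfg.get("arch", {})
    if arch_cfg:
        over["arch"] = ArchitectureParams(
            h1_sq=float(arch_cfg.get("h1_sq", 0.5)),
            h2_sq=float(arch_cfg.get("h2_sq", 0.5)),
            rho_ge=float(arch_cfg.get("rho_ge", 0.5)),
            p_causal=float(arch_cfg.get("p_causal", 0.99)),
            M=int(cfg.get("snps", {}).get("M", 8000)),
            effect_scale=str(arch_cfg.get("effect_scale", "standardized")),
        )
    if "replicates" in cfg:
        over["n_replicates"] = int(cfg["replicates"])
    if "seed" in cfg:
        over["base_seed"] = int(cfg["seed"])
    return default_scenario(**over)
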