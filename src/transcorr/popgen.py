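"""Synthetic diverged-population genotype panels with linkage disequilibrium.

Stands in for real haplotype resources: allele frequencies diverge from a
shared ancestral frequency under the Balding-Nichols drift model, and
haplotypes carry distance-decaying LD generated by thresholding a latent
stationary Gaussian AR(1) process.  Also provides two-way admixture with
ancestry-block mosaics (long-range LD), the QC filters applied to GWAS
cohorts (minor-allele-frequency and kinship thresholds, cross-population
SNP intersection) and seeded reference-panel subsampling.

Coordinates are 0-based SNP indices; "distance" means index difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "AncestralFrequencies",
    "PopulationModel",
    "GenotypeDataset",
    "QCThresholds",
    "draw_ancestral_frequencies",
    "draw_population_frequencies",
    "simulate_genotypes",
    "simulate_admixed",
    "filter_maf",
    "filter_related",
    "intersect_snps",
    "sample_reference_panel",
    "write_genotypes",
    "read_genotypes",
    "write_vcf",
]

_FREQ_CLIP = (0.001, 0.999)


@dataclass
class AncestralFrequencies:
    """Per-SNP allele frequencies of the (unobserved) ancestral population."""

    freqs: np.ndarray
    positions: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.positions is None:
            self.positions = np.arange(self.freqs.size)
        self.positions = np.asarray(self.positions)
        if not np.all(np.isfinite(self.freqs)):
            raise ValueError("ancestral frequencies must be finite")
        if np.any((self.freqs <= 0.0) | (self.freqs >= 1.0)):
            raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_snps(self) -> int:
        return int(self.freqs.size)


@dataclass(frozen=True)
class PopulationModel:
    """Drift and LD parameters of one simulated population.

    fst
        Balding-Nichols drift away from the ancestral frequencies, in (0,1).
    ld_rho
        Lag-1 autocorrelation of the latent Gaussian haplotype process, in
        [0,1); haplotypic LD decays geometrically with SNP-index distance.
    """

    fst: float
    ld_rho: float
    label: str = "pop"

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")


@dataclass
class GenotypeDataset:
    """Individuals x SNPs dosage matrix with sample allele frequencies.

    ``freqs`` always equals column means of ``dosages`` divided by 2.
    ``haplotypes`` (2n x M, phased, row 2i and 2i+1 belong to individual i)
    is kept when the dataset may seed an admixture mosaic.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    population: str = "pop"
    haplotypes: np.ndarray | None = None
    freqs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.snp_ids = np.asarray(self.snp_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if self.snp_ids.size != self.dosages.shape[1]:
            raise ValueError("snp_ids length must match dosage columns")
        computed = self.dosages.mean(axis=0, dtype=np.float64) / 2.0
        if self.freqs is None:
            self.freqs = computed
        elif not np.allclose(self.freqs, computed, atol=1e-8):
            raise ValueError("freqs inconsistent with dosage column means / 2")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes)
            if self.haplotypes.shape != (2 * self.n_individuals, self.n_snps):
                raise ValueError("haplotypes must have shape (2n, M)")

    @property
    def n_individuals(self) -> int:
        return int(self.dosages.shape[0])

    @property
    def n_snps(self) -> int:
        return int(self.dosages.shape[1])

    def select_snps(self, index: np.ndarray) -> "GenotypeDataset":
        """Restrict to SNP columns given by integer ``index`` (order kept)."""
        haps = None if self.haplotypes is None else self.haplotypes[:, index]
        return GenotypeDataset(
            dosages=self.dosages[:, index],
            snp_ids=self.snp_ids[index],
            population=self.population,
            haplotypes=haps,
        )

    def select_individuals(self, index: np.ndarray) -> "GenotypeDataset":
        """Restrict to individuals given by integer ``index`` (order kept)."""
        haps = None
        if self.haplotypes is not None:
            hap_index = np.column_stack([2 * index, 2 * index + 1]).ravel()
            haps = self.haplotypes[hap_index]
        return GenotypeDataset(
            dosages=self.dosages[index],
            snp_ids=self.snp_ids,
            population=self.population,
            haplotypes=haps,
        )


@dataclass(frozen=True)
class QCThresholds:
    """Cohort quality-control thresholds.

    f0 : minimum minor allele frequency kept (paper-style MAF filter).
    r0 : maximum pairwise kinship coefficient tolerated between individuals.
    """

    f0: float = 0.01
    r0: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.f0 < 0.5):
            raise ValueError("f0 must satisfy 0 <= f0 < 0.5")
        if not (0.0 < self.r0 <= 0.5):
            raise ValueError("r0 must satisfy 0 < r0 <= 0.5")


def draw_ancestral_frequencies(
    n_snps: int,
    seed: int | np.random.Generator,
    low: float = 0.05,
    high: float = 0.95,
) -> AncestralFrequencies:
    """Uniform ancestral allele frequencies on [low, high], one per SNP."""
    rng = np.random.default_rng(seed)
    return AncestralFrequencies(freqs=rng.uniform(low, high, size=n_snps))


def draw_population_frequencies(
    ancestral: AncestralFrequencies,
    model: PopulationModel,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Drift ancestral frequencies into one population (Balding-Nichols).

    Each SNP's population frequency is drawn from
    Beta(f (1-F)/F, (1-f)(1-F)/F) with F = ``model.fst``, whose mean is the
    ancestral frequency f and variance F f (1-f), then clipped away from the
    degenerate boundaries.
    """
    rng = np.random.default_rng(seed)
    f = ancestral.freqs
    scale = (1.0 - model.fst) / model.fst
    out = rng.beta(f * scale, (1.0 - f) * scale)
    return np.clip(out, *_FREQ_CLIP)


def _simulate_haplotypes(
    pop_freqs: np.ndarray,
    ld_rho: float,
    n_haplotypes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Threshold a latent stationary AR(1) Gaussian into 0/1 haplotypes.

    The latent process has unit marginal variance and lag-k autocorrelation
    ld_rho**k; thresholding at the per-SNP normal quantile of the target
    frequency gives binary alleles with that frequency and geometrically
    decaying haplotypic LD.
    """
    m = pop_freqs.size
    # SNP-major layout keeps the AR(1) recurrence on contiguous rows
    latent = rng.standard_normal((m, n_haplotypes), dtype=np.float32)
    if ld_rho > 0.0:
        c = np.float32(np.sqrt(1.0 - ld_rho * ld_rho))
        r = np.float32(ld_rho)
        for j in range(1, m):
            latent[j] *= c
            latent[j] += r * latent[j - 1]
    thresholds = sps.norm.ppf(pop_freqs).astype(np.float32)
    alleles = np.empty((m, n_haplotypes), dtype=np.uint8)
    np.less(latent, thresholds[:, None], out=alleles.view(bool))
    return alleles.T  # (n_hap, m) view; SNP-major storage avoids big transposed copies


def simulate_genotypes(
    pop_freqs: np.ndarray,
    model: PopulationModel,
    n_individuals: int,
    seed: int | np.random.Generator,
    snp_ids: np.ndarray | None = None,
    keep_haplotypes: bool = False,
) -> GenotypeDataset:
    """Simulate unrelated diploid genotypes with AR(1)-decaying LD.

    Each individual is the sum of two independent haplotypes from
    :func:`_simulate_haplotypes`; LD between SNPs i and j decays
    geometrically in |i - j|.
    """
    pop_freqs = np.asarray(pop_freqs, dtype=float)
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if np.any((pop_freqs <= 0.0) | (pop_freqs >= 1.0)):
        raise ValueError("population frequencies must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    haps = _simulate_haplotypes(pop_freqs, model.ld_rho, 2 * n_individuals, rng)
    dosages = haps[0::2] + haps[1::2]
    if snp_ids is None:
        snp_ids = np.array([f"snp{i}" for i in range(pop_freqs.size)])
    return GenotypeDataset(
        dosages=dosages,
        snp_ids=np.asarray(snp_ids),
        population=model.label,
        haplotypes=haps if keep_haplotypes else None,
    )


def simulate_admixed(
    panel_a: GenotypeDataset,
    panel_b: GenotypeDataset,
    admix_prop: float,
    block_len: int,
    n_individuals: int,
    seed: int | np.random.Generator,
    label: str = "admixed",
    prop_concentration: float | None = 10.0,
) -> GenotypeDataset:
    """Two-way admixture: haplotypes are mosaics of ancestry blocks.

    Each individual first draws a personal ancestry proportion theta from
    Beta(nu*p, nu*(1-p)) with p = ``admix_prop`` and concentration
    nu = ``prop_concentration`` (African-American-like spread of global
    ancestry at the default); every ``block_len`` consecutive SNPs of each
    of the individual's haplotypes then come from a random source haplotype
    of panel a (with probability theta) or panel b.  Between-individual
    variation in theta is what induces long-range LD between SNPs in
    different blocks whose frequencies differ between the sources
    (admixture LD) -- with a fixed proportion (``prop_concentration=None``)
    ancestry blocks are independent and only the strong within-block mosaic
    LD remains.
    """
    if panel_a.haplotypes is None or panel_b.haplotypes is None:
        raise ValueError("source panels must carry haplotypes (keep_haplotypes=True)")
    if panel_a.n_snps != panel_b.n_snps or np.any(panel_a.snp_ids != panel_b.snp_ids):
        raise ValueError("source panels must share the same SNP set and order")
    if not (0.0 < admix_prop <= 1.0):
        raise ValueError("admix_prop must be in (0, 1]")
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    rng = np.random.default_rng(seed)
    m = panel_a.n_snps
    n_hap = 2 * n_individuals
    bounds = list(range(0, m, block_len)) + [m]
    n_blocks = len(bounds) - 1
    if prop_concentration is None or admix_prop >= 1.0:
        theta = np.full(n_individuals, admix_prop)
    else:
        nu = prop_concentration
        theta = rng.beta(nu * admix_prop, nu * (1.0 - admix_prop), size=n_individuals)
    from_a = rng.random((n_hap, n_blocks)) < np.repeat(theta, 2)[:, None]
    rows_a = rng.integers(0, panel_a.haplotypes.shape[0], size=(n_hap, n_blocks))
    rows_b = rng.integers(0, panel_b.haplotypes.shape[0], size=(n_hap, n_blocks))
    haps = np.empty((n_hap, m), dtype=np.uint8)
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        block = np.where(
            from_a[:, b : b + 1],
            panel_a.haplotypes[rows_a[:, b], sl],
            panel_b.haplotypes[rows_b[:, b], sl],
        )
        haps[:, sl] = block
    return GenotypeDataset(
        dosages=haps[0::2] + haps[1::2],
        snp_ids=panel_a.snp_ids,
        population=label,
        haplotypes=haps,
    )


def filter_maf(data: GenotypeDataset, f0: float) -> GenotypeDataset:
    """Keep SNPs whose minor allele frequency is at least ``f0``."""
    maf = np.minimum(data.freqs, 1.0 - data.freqs)
    keep = np.flatnonzero(maf >= f0)
    if keep.size == 0:
        raise ValueError(f"MAF filter at f0={f0} removed every SNP")
    return data.select_snps(keep)


def filter_related(data: GenotypeDataset, r0: float) -> GenotypeDataset:
    """Remove individuals until no pairwise kinship exceeds ``r0``.

    Kinship is estimated as half the Pearson correlation of standardized
    genotype vectors (0.5 for duplicates, ~0 for unrelateds).  From every
    violating pair the higher-index individual is removed first, greedily,
    so the result is deterministic.
    """
    if data.n_snps < 2:
        raise ValueError("kinship estimation needs at least 2 SNPs")
    # per-SNP (column) standardization first, so shared allele-frequency
    # structure does not masquerade as relatedness
    x = data.dosages.astype(np.float64)
    x -= x.mean(axis=0, keepdims=True)
    col_sd = x.std(axis=0)
    x = x[:, col_sd > 0.0] / col_sd[col_sd > 0.0]
    norms = np.sqrt((x * x).sum(axis=1))
    norms[norms == 0.0] = np.nan
    x /= norms[:, None]
    kinship = 0.5 * (x @ x.T)
    np.fill_diagonal(kinship, 0.0)
    alive = np.ones(data.n_individuals, dtype=bool)
    with np.errstate(invalid="ignore"):
        exceed = np.nan_to_num(kinship) > r0
    while True:
        violating = exceed & alive[:, None] & alive[None, :]
        if not violating.any():
            break
        worst = np.max(np.flatnonzero(violating.any(axis=1)))
        alive[worst] = False
    return data.select_individuals(np.flatnonzero(alive))


def intersect_snps(
    pop1: GenotypeDataset, pop2: GenotypeDataset
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Restrict both datasets to SNPs present and polymorphic in both.

    Output order follows pop1's SNP order; both outputs share it.
    """
    poly1 = (pop1.freqs > 0.0) & (pop1.freqs < 1.0)
    poly2 = (pop2.freqs > 0.0) & (pop2.freqs < 1.0)
    ok2 = {sid for sid, p in zip(pop2.snp_ids, poly2) if p}
    idx1 = np.flatnonzero([p and (sid in ok2) for sid, p in zip(pop1.snp_ids, poly1)])
    if idx1.size == 0:
        raise ValueError("no common polymorphic SNPs between the two datasets")
    pos2 = {sid: i for i, sid in enumerate(pop2.snp_ids)}
    idx2 = np.array([pos2[sid] for sid in pop1.snp_ids[idx1]])
    return pop1.select_snps(idx1), pop2.select_snps(idx2)


def sample_reference_panel(
    data: GenotypeDataset, L: int, seed: int | np.random.Generator
) -> GenotypeDataset:
    """Draw L individuals without replacement as an external reference panel."""
    if L > data.n_individuals:
        raise ValueError(f"L={L} exceeds the {data.n_individuals} individuals available")
    if L <= 2:
        raise ValueError("L must exceed 2 for LD correlations to be defined")
    rng = np.random.default_rng(seed)
    rows = rng.choice(data.n_individuals, size=L, replace=False)
    return data.select_individuals(rows)


# --------------------------------------------------------------------------
# text import/export


def write_genotypes(data: GenotypeDataset, path) -> None:
    """Whitespace-delimited dosage matrix; header row carries SNP ids."""
    with open(path, "w") as fh:
        fh.write(" ".join(str(s) for s in data.snp_ids) + "\n")
        np.savetxt(fh, data.dosages, fmt="%d", delimiter=" ")


def read_genotypes(path, population: str = "pop") -> GenotypeDataset:
    with open(path) as fh:
        snp_ids = np.array(fh.readline().split())
        dosages = np.loadtxt(fh, dtype=np.uint8, ndmin=2)
    if dosages.shape[1] != snp_ids.size:
        raise ValueError("genotype matrix width does not match header SNP count")
    return GenotypeDataset(dosages=dosages, snp_ids=snp_ids, population=population)


def write_vcf(data: GenotypeDataset, path, contig: str = "1") -> None:
    """Minimal GT-only VCF export of the dosage matrix (one contig).

    Dosages are written as unphased genotypes (0 -> 0/0, 1 -> 0/1, 2 -> 1/1)
    with placeholder alleles A/G; positions are 1-based SNP indices.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = [f"ind{i}" for i in range(data.n_individuals)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={data.n_snps + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(data.n_snps):
            gts = "\t".join(gt_map[int(d)] for d in data.dosages[:, j])
            fh.write(f"{contig}\t{j + 1}\t{data.snp_ids[j]}\tA\tG\t.\t.\t.\tGT\t{gts}\n")
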