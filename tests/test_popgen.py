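"""Population simulator: drift, LD decay, admixture and QC filters."""

import numpy as np
import pytest
from scipy import stats as sps

from transcorr import (
    AncestralFrequencies,
    PopulationModel,
    draw_population_frequencies,
    filter_maf,
    filter_related,
    intersect_snps,
    read_genotypes,
    sample_reference_panel,
    simulate_admixed,
    simulate_genotypes,
    write_genotypes,
    write_vcf,
)

from conftest import dataset_from_dosages


class TestBaldingNichols:
    def test_zero_drift_limit_recovers_ancestral_frequency(self):
        anc = AncestralFrequencies(freqs=np.full(200, 0.5))
        model = PopulationModel(fst=1e-6, ld_rho=0.0)
        f = draw_population_frequencies(anc, model, seed=0)
        assert np.allclose(f, 0.5, atol=0.01)

    def test_beta_moments(self):
        # mean f, variance F f (1-f) of the Balding-Nichols distribution
        anc = AncestralFrequencies(freqs=np.full(10_000, 0.3))
        model = PopulationModel(fst=0.15, ld_rho=0.0)
        f = draw_population_frequencies(anc, model, seed=1)
        expected_var = 0.15 * 0.3 * 0.7
        assert abs(f.mean() - 0.3) < 0.01
        assert abs(f.var() - expected_var) < 0.2 * expected_var

    def test_deterministic_given_seed(self):
        anc = AncestralFrequencies(freqs=np.linspace(0.1, 0.9, 50))
        model = PopulationModel(fst=0.11, ld_rho=0.9)
        a = draw_population_frequencies(anc, model, seed=42)
        b = draw_population_frequencies(anc, model, seed=42)
        assert np.array_equal(a, b)

    def test_rejects_nonfinite_ancestral(self):
        with pytest.raises(ValueError):
            AncestralFrequencies(freqs=np.array([0.5, np.nan]))

    def test_output_clipped_inside_unit_interval(self):
        anc = AncestralFrequencies(freqs=np.full(2000, 0.01))
        f = draw_population_frequencies(anc, PopulationModel(fst=0.5, ld_rho=0.0), seed=2)
        assert f.min() >= 0.001 and f.max() <= 0.999


def _binary_corr_from_latent(rho_latent: float, f: float) -> float:
    """Oracle: correlation of thresholded indicators via the BVN orthant mass."""
    t = sps.norm.ppf(f)
    p11 = sps.multivariate_normal(mean=[0, 0], cov=[[1, rho_latent], [rho_latent, 1]]).cdf([t, t])
    return (p11 - f * f) / (f * (1 - f))


class TestSimulateGenotypes:
    def test_no_ld_limit(self):
        freqs = np.full(1000, 0.5)
        model = PopulationModel(fst=0.11, ld_rho=0.0)
        data = simulate_genotypes(freqs, model, 400, seed=3)
        g = data.dosages.astype(float)
        cors = [
            np.corrcoef(g[:, j], g[:, j + 1])[0, 1] for j in range(0, 999, 2)
        ]
        assert abs(np.mean(cors)) < 0.05

    def test_haplotype_ld_decay_matches_orthant_oracle(self):
        freqs = np.full(400, 0.5)
        model = PopulationModel(fst=0.11, ld_rho=0.9)
        data = simulate_genotypes(freqs, model, 2500, seed=4, keep_haplotypes=True)
        h = data.haplotypes.astype(float)
        mean_r = []
        for lag in range(1, 6):
            r = [
                np.corrcoef(h[:, j], h[:, j + lag])[0, 1]
                for j in range(0, 400 - lag, 20)
            ]
            mean_r.append(np.mean(r))
        assert 0.5 < mean_r[0] < 0.95
        assert all(a > b for a, b in zip(mean_r, mean_r[1:]))  # monotone decay
        for lag, observed in enumerate(mean_r, start=1):
            assert observed == pytest.approx(
                _binary_corr_from_latent(0.9**lag, 0.5), abs=0.05
            )

    def test_frequencies_reproduced(self):
        rng = np.random.default_rng(5)
        freqs = rng.uniform(0.05, 0.95, 300)
        model = PopulationModel(fst=0.11, ld_rho=0.9)
        data = simulate_genotypes(freqs, model, 5000, seed=6)
        assert np.max(np.abs(data.freqs - freqs)) < 0.02

    def test_rejects_boundary_frequency(self):
        model = PopulationModel(fst=0.11, ld_rho=0.5)
        with pytest.raises(ValueError):
            simulate_genotypes(np.array([0.0, 0.5]), model, 10, seed=0)


class TestSimulateAdmixed:
    @staticmethod
    def _sources(fa, fb, n=2000, seed=0):
        model = PopulationModel(fst=0.11, ld_rho=0.0)
        a = simulate_genotypes(fa, model, n, seed=seed, keep_haplotypes=True)
        b = simulate_genotypes(fb, model, n, seed=seed + 1, keep_haplotypes=True)
        return a, b

    def test_degenerate_mixture_is_source_a(self):
        fa = np.full(100, 0.8)
        fb = np.full(100, 0.2)
        a, b = self._sources(fa, fb, n=1500)
        adm = simulate_admixed(a, b, admix_prop=1.0, block_len=10, n_individuals=1500, seed=2)
        assert np.max(np.abs(adm.freqs - 0.8)) < 0.04  # sampling error only

    def test_cross_block_admixture_ld(self):
        # SNPs 10 blocks apart; delta = 0.5 at both; oracle: cross-block
        # genotype covariance 4 Var(theta) delta_i delta_j from the variable
        # individual ancestry proportion
        m, bl = 600, 50
        fa = np.full(m, 0.75)
        fb = np.full(m, 0.25)
        a, b = self._sources(fa, fb, n=3000, seed=3)
        adm = simulate_admixed(
            a, b, admix_prop=0.5, block_len=bl, n_individuals=3000, seed=4,
            prop_concentration=3.0,
        )
        i, j = 25, 25 + 10 * bl
        r2_adm = np.corrcoef(adm.dosages[:, i].astype(float), adm.dosages[:, j].astype(float))[0, 1] ** 2
        for src in (a, b):
            r2_src = np.corrcoef(src.dosages[:, i].astype(float), src.dosages[:, j].astype(float))[0, 1] ** 2
            assert r2_adm > r2_src
        var_theta = 0.25 / (3.0 + 1.0)  # Beta(1.5, 1.5)
        cov_oracle = 4 * var_theta * 0.5 * 0.5
        cov_obs = np.cov(adm.dosages[:, i].astype(float), adm.dosages[:, j].astype(float))[0, 1]
        assert cov_obs == pytest.approx(cov_oracle, abs=0.03)

    def test_fixed_proportion_gives_no_cross_block_ld(self):
        m, bl = 200, 20
        fa = np.full(m, 0.75)
        fb = np.full(m, 0.25)
        a, b = self._sources(fa, fb, n=4000, seed=5)
        adm = simulate_admixed(
            a, b, admix_prop=0.5, block_len=bl, n_individuals=4000, seed=6,
            prop_concentration=None,
        )
        i, j = 10, 10 + 5 * bl
        r = np.corrcoef(adm.dosages[:, i].astype(float), adm.dosages[:, j].astype(float))[0, 1]
        assert abs(r) < 0.05

    def test_single_block_when_block_len_exceeds_m(self):
        fa = np.full(50, 0.9)
        fb = np.full(50, 0.1)
        a, b = self._sources(fa, fb, n=300, seed=7)
        adm = simulate_admixed(a, b, admix_prop=0.5, block_len=100, n_individuals=300, seed=8)
        # every haplotype matches one source's frequency profile wholesale:
        # per-haplotype mean allele count is bimodal around 0.9 or 0.1
        hap_means = adm.haplotypes.mean(axis=1)
        assert np.all((hap_means > 0.6) | (hap_means < 0.4))

    def test_mismatched_snp_sets_rejected(self):
        fa = np.full(20, 0.5)
        a, b = self._sources(fa, fa, n=50, seed=9)
        b2 = b.select_snps(np.arange(10))
        with pytest.raises(ValueError):
            simulate_admixed(a, b2, 0.5, 5, 10, seed=0)


class TestQCFilters:
    def test_maf_filter_counts(self):
        data = dataset_from_dosages(
            np.array([[0, 0, 1], [0, 1, 1], [1, 0, 0], [0, 0, 1]] * 125)
        )
        # sample freqs: 0.125, 0.125, 0.375 -> craft explicit threshold cases
        kept = filter_maf(data, f0=0.2)
        assert kept.n_snps == 1

    def test_maf_zero_is_identity(self):
        data = dataset_from_dosages(np.array([[0, 1], [1, 2], [2, 1]]))
        assert filter_maf(data, 0.0).n_snps == 2

    def test_maf_symmetric_in_minor_allele(self):
        # frequency 0.996 has minor allele 0.004 and must be removed at f0=0.01
        col = np.full((250, 1), 2, dtype=np.uint8)
        col[0, 0] = 0  # freq = 498/500 = 0.996
        col2 = np.tile([0, 1, 2, 1], 250)[:250].reshape(250, 1)
        data = dataset_from_dosages(np.hstack([col, col2]))
        with pytest.raises(ValueError):
            filter_maf(data.select_snps(np.array([0])), 0.01)
        kept = filter_maf(data, 0.01)
        assert kept.n_snps == 1 and kept.snp_ids[0] == "snp1"

    def test_duplicate_individual_removed(self, rng):
        dos = rng.integers(0, 3, size=(30, 5000)).astype(np.uint8)
        dos[17] = dos[3]  # duplicate pair -> kinship ~ 0.5
        data = dataset_from_dosages(dos)
        kept = filter_related(data, r0=0.05)
        assert kept.n_individuals == 29
        # deterministic: the higher index of the pair is the one dropped
        assert np.array_equal(kept.dosages[3], dos[3])

    def test_unrelated_individuals_retained(self):
        model = PopulationModel(fst=0.11, ld_rho=0.0)
        freqs = np.random.default_rng(0).uniform(0.1, 0.9, 5000)
        data = simulate_genotypes(freqs, model, 100, seed=10)
        kept = filter_related(data, r0=0.05)
        assert kept.n_individuals >= 99

    def test_loose_threshold_is_identity(self, rng):
        data = dataset_from_dosages(rng.integers(0, 3, size=(20, 300)).astype(np.uint8))
        assert filter_related(data, r0=0.5).n_individuals == 20

    def test_intersect_by_id_and_polymorphism(self):
        d1 = dataset_from_dosages(
            np.array([[0, 1, 2], [1, 1, 0], [2, 1, 1]]), snp_ids=["a", "b", "c"]
        )
        d2 = dataset_from_dosages(
            np.array([[2, 1, 0], [0, 1, 1], [1, 0, 2]]), snp_ids=["b", "c", "d"]
        )
        o1, o2 = intersect_snps(d1, d2)
        assert list(o1.snp_ids) == ["b", "c"] == list(o2.snp_ids)

    def test_intersect_identity(self):
        d = dataset_from_dosages(np.array([[0, 1], [2, 1], [1, 0]]))
        o1, o2 = intersect_snps(d, d)
        assert np.array_equal(o1.dosages, d.dosages)
        assert np.array_equal(o2.dosages, d.dosages)

    def test_monomorphic_in_one_population_excluded(self):
        d1 = dataset_from_dosages(np.array([[0, 1], [1, 2], [2, 0]]), snp_ids=["a", "b"])
        d2 = dataset_from_dosages(np.array([[0, 2], [0, 1], [0, 0]]), snp_ids=["a", "b"])
        o1, o2 = intersect_snps(d1, d2)
        assert list(o1.snp_ids) == ["b"] == list(o2.snp_ids)

    def test_qc_commutes_with_intersection(self):
        rng = np.random.default_rng(11)
        model = PopulationModel(fst=0.11, ld_rho=0.3)
        freqs = rng.uniform(0.01, 0.99, 400)
        d1 = simulate_genotypes(freqs, model, 300, seed=12)
        d2 = simulate_genotypes(freqs, model, 300, seed=13)
        a1, a2 = intersect_snps(filter_maf(d1, 0.05), filter_maf(d2, 0.05))
        b1, b2 = intersect_snps(d1, d2)
        b1, b2 = intersect_snps(filter_maf(b1, 0.05), filter_maf(b2, 0.05))
        assert list(a1.snp_ids) == list(b1.snp_ids)
        assert list(a2.snp_ids) == list(b2.snp_ids)


class TestReferencePanel:
    def test_full_panel_is_permutation(self, rng):
        data = dataset_from_dosages(rng.integers(0, 3, (10, 5)).astype(np.uint8))
        panel = sample_reference_panel(data, L=10, seed=0)
        order = np.lexsort(panel.dosages.T)
        base = np.lexsort(data.dosages.T)
        assert np.array_equal(panel.dosages[order], data.dosages[base])

    def test_deterministic_selection(self, rng):
        data = dataset_from_dosages(rng.integers(0, 3, (50, 5)).astype(np.uint8))
        p1 = sample_reference_panel(data, L=20, seed=9)
        p2 = sample_reference_panel(data, L=20, seed=9)
        assert np.array_equal(p1.dosages, p2.dosages)

    @pytest.mark.parametrize("L", [2, 51])
    def test_invalid_sizes_rejected(self, rng, L):
        data = dataset_from_dosages(rng.integers(0, 3, (50, 5)).astype(np.uint8))
        with pytest.raises(ValueError):
            sample_reference_panel(data, L=L, seed=0)


class TestGenotypeIO:
    def test_text_round_trip(self, rng, tmp_path):
        data = dataset_from_dosages(rng.integers(0, 3, (12, 7)).astype(np.uint8))
        path = tmp_path / "geno.txt"
        write_genotypes(data, path)
        back = read_genotypes(path)
        assert np.array_equal(back.dosages, data.dosages)
        assert list(back.snp_ids) == list(data.snp_ids)

    def test_vcf_readable_by_pysam(self, rng, tmp_path):
        import pysam

        data = dataset_from_dosages(rng.integers(0, 3, (5, 4)).astype(np.uint8))
        path = tmp_path / "geno.vcf"
        write_vcf(data, path)
        recs = list(pysam.VariantFile(str(path)))
        assert len(recs) == 4
        dosage = np.array(
            [[sum(rec.samples[s]["GT"]) for s in rec.samples] for rec in recs]
        ).T
        assert np.array_equal(dosage, data.dosages)
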