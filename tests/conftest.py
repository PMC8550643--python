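import numpy as np
import pytest

from transcorr import (
    ArchitectureParams,
    GenotypeDataset,
    PopulationModel,
    default_scenario,
)


def dataset_from_dosages(dosages, snp_ids=None, population="pop") -> GenotypeDataset:
    """Build a GenotypeDataset directly from an explicit dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.uint8)
    if snp_ids is None:
        snp_ids = np.array([f"snp{i}" for i in range(dosages.shape[1])])
    return GenotypeDataset(dosages=dosages, snp_ids=np.asarray(snp_ids), population=population)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_model():
    return PopulationModel(fst=0.11, ld_rho=0.9, label="pop1")


def reduced_scenario(**overrides):
    """Desk-scale-but-small scenario used by the heavier integration tests."""
    arch = overrides.pop(
        "arch", ArchitectureParams(h1_sq=0.5, h2_sq=0.5, rho_ge=0.5, p_causal=0.99, M=2000)
    )
    base = dict(N1=4000, N2=4000, M=2000, L=500, arch=arch)
    base.update(overrides)
    return default_scenario(**base)


@pytest.fixture(scope="session")
def default_run():
    """The 30-replicate default scenario shared by the acceptance checks.

    Session-scoped: the replicates take a few minutes and three separate
    criteria (unbiasedness, stability, jackknife calibration) read them.
    """
    from transcorr.evaluation import run_scenario, summarize

    scenario = default_scenario(base_seed=1)
    fits, truth, failures = run_scenario(scenario)
    return summarize(fits, truth, n_failures=len(failures))
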