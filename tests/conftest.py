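import numpy as np
import pytest

from popnovel.synthetic_data import (
    SimulationConfig,
    simulate_cohort_vcf,
    simulate_gene_models,
    simulate_panels,
    simulate_populations,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_sites=2000, pca_n_sites=800,
                            n_pop_samples=60)


@pytest.fixture(scope="session")
def gene_sim(small_config, tmp_path_factory):
    return simulate_gene_models(small_config, tmp_path_factory.mktemp("genes"))


@pytest.fixture(scope="session")
def cohort(small_config, gene_sim, tmp_path_factory):
    """(vcf_path, GroundTruth) for the default small synthetic cohort."""
    out = tmp_path_factory.mktemp("cohort")
    return simulate_cohort_vcf(small_config, out / "cohort.vcf",
                               genome=gene_sim.genome)


@pytest.fixture(scope="session")
def panels(small_config, cohort, tmp_path_factory):
    _, truth = cohort
    return simulate_panels(small_config, truth,
                           tmp_path_factory.mktemp("panels"))


@pytest.fixture(scope="session")
def population_sim(small_config):
    return simulate_populations(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
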