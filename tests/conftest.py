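import pytest

from regulon_forge.simulate import (
    SimulationConfig,
    simulate_gene_models_and_de,
    simulate_genome_and_peaks,
    simulate_mark_peaks,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        genome_length=60_000,
        n_chromosomes=2,
        planted_runs=(("GGAA", 3, 4), ("TTCC", 5, 3), ("GGAA", 1, 6)),
        n_peaks=25,
        n_genes=80,
        n_tracks=6,
        n_null_genes=30,
        cohort_n_tumors=20,
        cohort_n_celllines=12,
    )


@pytest.fixture(scope="session")
def genome_peaks(small_config):
    return simulate_genome_and_peaks(small_config)


@pytest.fixture(scope="session")
def gene_de(small_config):
    return simulate_gene_models_and_de(small_config)


@pytest.fixture(scope="session")
def mark_truth(small_config, gene_de):
    return simulate_mark_peaks(small_config, gene_de.genes)
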