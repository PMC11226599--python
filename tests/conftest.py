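import pytest
from hypothesis import settings

from varlens.synthetic import SimulationConfig, simulate_ecosystem

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_individuals=100,
        n_colonies=8,
        n_genes=10,
        mean_cds_length_codons=150,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_ecosystem(small_config):
    """One shared small synthetic ecosystem (no files written)."""
    return simulate_ecosystem(small_config)
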