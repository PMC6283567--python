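import numpy as np
import pytest

from rarestrat import DemographyConfig, simulate_two_pop


@pytest.fixture(scope="session")
def tiny_demography() -> DemographyConfig:
    """Small, fast configuration for unit tests (not the study conditions)."""
    return DemographyConfig(
        deme_haplotypes=400,
        migration_rate=0.01,
        region_length_bp=5_000,
    )


@pytest.fixture(scope="session")
def tiny_panel(tiny_demography):
    return simulate_two_pop(tiny_demography, seed=11)[0]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
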