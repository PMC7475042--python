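import logging

import pytest
from hypothesis import HealthCheck, settings

from paralocus.pipeline import PipelineConfig
from paralocus.simulate import (
    VARIANT_POSITIONS,
    preset,
    simulate_individual,
    synthetic_sun_catalog,
)

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

logging.getLogger("paralocus").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def catalog():
    """Shared synthetic SUN catalog over the default multicopy region."""
    return synthetic_sun_catalog(seed=0)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(variant_sites=VARIANT_POSITIONS)


@pytest.fixture(scope="session")
def modal_individual(catalog):
    """One modal-human genome (ten alleles, two per locus) at 30x."""
    return simulate_individual(preset("modern_human_standard", 30, seed=42), catalog, "modal")
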