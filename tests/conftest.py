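import numpy as np
import pandas as pd
import pytest

from respburden.config import WorldConfig
from respburden.synthworld import generate_world


@pytest.fixture(scope="session")
def demo_config() -> WorldConfig:
    """The 6-location demo world at 100 draws."""
    return WorldConfig(n_draws=100, seed=20150901)


@pytest.fixture(scope="session")
def demo_world(demo_config):
    return generate_world(demo_config)


@pytest.fixture(scope="session")
def tiny_config() -> WorldConfig:
    """Two locations, one year, three old-age bands: fast sampling tests."""
    return WorldConfig(
        n_locations=2,
        years=(2005,),
        age_starts=(50, 55, 60),
        n_draws=10,
        seed=42,
        survey_sample_size=500,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return generate_world(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
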