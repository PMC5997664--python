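import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_unit():
    from scadapt.population import default_unit

    return default_unit()


@pytest.fixture(scope="session")
def model_params():
    from scadapt.model import ModelParameters

    return ModelParameters()


@pytest.fixture(scope="session")
def fast_sim():
    """Small-extent simulation settings for model property tests."""
    return dict(dt=0.005, grid_spacing=1.0, extent=40.0)
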