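import numpy as np
import pytest
from hypothesis import settings

from beamforce.registry import default_registry

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def laser(registry):
    return registry.laser


@pytest.fixture(scope="session")
def beam1(registry):
    return registry.beam("beam1")


@pytest.fixture(scope="session")
def fem1(registry):
    return registry.calibration("beam1", "fem")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
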