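import numpy as np
import pytest

from pdadose.sensor_model import ArrayLayout, GeneratorConfig


@pytest.fixture(scope="session")
def config() -> GeneratorConfig:
    return GeneratorConfig()

@pytest.fixture(scope="session")
def layout() -> ArrayLayout:
    return ArrayLayout()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
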