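import numpy as np
import pytest

from selexdyn import presets


@pytest.fixture(scope="session")
def hammerhead():
    return presets.hammerhead_structure()


@pytest.fixture(scope="session")
def twister():
    return presets.twister_structure()


@pytest.fixture(scope="session")
def triphosphorylation():
    return presets.triphosphorylation_structure()


@pytest.fixture(scope="session")
def toy():
    return presets.toy_structure()


@pytest.fixture(scope="session")
def toy_two_module():
    return presets.toy_two_module_structure()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
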