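import numpy as np
import pytest

from mcrscreen import (
    ExposureScenario,
    load_default_permitted_doses,
)


@pytest.fixture(scope="session")
def pd_table():
    return load_default_permitted_doses()


@pytest.fixture()
def scenario():
    return ExposureScenario()


@pytest.fixture()
def rng():
    return np.random.default_rng(20110616)
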