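import numpy as np
import pytest

from forestfolio import (
    CostTable,
    EconParams,
    default_scenarios,
    generate_enterprise,
)
from forestfolio.simulate import default_hazard_models


@pytest.fixture(scope="session")
def enterprise():
    return generate_enterprise(6, 250.0, seed=1)


@pytest.fixture(scope="session")
def models():
    return default_hazard_models()


@pytest.fixture(scope="session")
def costs():
    return CostTable()


@pytest.fixture(scope="session")
def econ():
    return EconParams()


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
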