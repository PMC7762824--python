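import numpy as np
import pytest

from tcmodel.circuit_model import ParameterVector, build_cmc, build_tcm


@pytest.fixture(scope="session")
def tcm_spec():
    return build_tcm()


@pytest.fixture(scope="session")
def cmc_spec():
    return build_cmc()


@pytest.fixture()
def tcm_params(tcm_spec):
    return ParameterVector.zeros(tcm_spec)


@pytest.fixture()
def cmc_params(cmc_spec):
    return ParameterVector.zeros(cmc_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
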