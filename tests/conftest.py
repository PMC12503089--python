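import numpy as np
import pytest

from immunodesign import (
    ErrorModel,
    InitialInformation,
    calibrate,
    optimal_design,
)
from immunodesign.robustness import SCENARIOS


@pytest.fixture(scope="session")
def error_model():
    return ErrorModel(sigma=0.25, rho=0.73)


@pytest.fixture(scope="session")
def scen1_info():
    return SCENARIOS[1].info


@pytest.fixture(scope="session")
def scen1_params(scen1_info):
    result = calibrate(scen1_info)
    assert result.converged
    return result.params


@pytest.fixture(scope="session")
def scen9_info():
    return SCENARIOS[9].info


@pytest.fixture(scope="session")
def scen9_params(scen9_info):
    result = calibrate(scen9_info)
    assert result.converged
    return result.params


@pytest.fixture(scope="session")
def scen1_design(scen1_params, scen1_info, error_model):
    return optimal_design(scen1_params, scen1_info, error_model)
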