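import numpy as np
import pytest

from mixdes import anova, fit
from mixdes import fixtures as fx


@pytest.fixture(scope="session")
def region():
    return fx.region()


@pytest.fixture(scope="session")
def table1_design():
    return fx.design()


@pytest.fixture(scope="session")
def table1_responses():
    return fx.responses()


@pytest.fixture(scope="session")
def ps_dtx_fit(table1_design, table1_responses):
    return fit(table1_design, table1_responses["ps_dtx"], "quadratic", "ps_dtx")


@pytest.fixture(scope="session")
def ps_ccm_fit(table1_design, table1_responses):
    return fit(table1_design, table1_responses["ps_ccm"], "quadratic", "ps_ccm")


@pytest.fixture(scope="session")
def vmd_dtx_fit(table1_design, table1_responses):
    return fit(table1_design, table1_responses["vmd_dtx"], "linear", "vmd_dtx")


@pytest.fixture(scope="session")
def ps_dtx_anova(ps_dtx_fit, table1_design):
    return anova(ps_dtx_fit, table1_design)


@pytest.fixture(scope="session")
def published_models():
    return {k: fx.published_model(k) for k in fx.RESPONSE_COLUMNS}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240357)
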