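import numpy as np
import pytest

from flaglen.datatypes import FlagellarGeometry, FrapModelParams, TransportParams
from flaglen.scenarios import get_scenario


@pytest.fixture(scope="session")
def wbc6():
    return get_scenario("wbc6")


@pytest.fixture(scope="session")
def anterior_geometry(wbc6):
    ps = wbc6.pair_stats("anterior")
    return FlagellarGeometry(
        pair="anterior",
        membrane_length=ps.membrane_mean,
        cytoplasmic_length=ps.cytoplasmic_mean,
    )


@pytest.fixture(scope="session")
def cyto_frap_params(wbc6):
    return FrapModelParams(**wbc6.frap["cytoplasmic"])


@pytest.fixture(scope="session")
def pore_frap_params(wbc6):
    return FrapModelParams(**wbc6.frap["pore"])


@pytest.fixture(scope="session")
def tip_frap_params(wbc6):
    return FrapModelParams(**wbc6.frap["tip"])


@pytest.fixture(scope="session")
def fig7_transport():
    return TransportParams(lambda_=0.25, v=1e-3, c_init=1e-3)


def assert_close(a, b, rtol=0.0, atol=0.0, msg=""):
    np.testing.assert_allclose(a, b, rtol=rtol, atol=atol, err_msg=msg)
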