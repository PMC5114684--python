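import pytest
from hypothesis import settings, HealthCheck

import mirsponge as ms

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Screening-profile Turner 2004 parameters (zero end terms)."""
    return ms.load_parameters("turner2004-screen")


@pytest.fixture(scope="session")
def params_full():
    """Absolute-dG profile (duplex initiation 4.09, terminal AU 0.45)."""
    return ms.load_parameters("turner2004")


@pytest.fixture(scope="session")
def limits():
    return ms.ScanLimits()


@pytest.fixture(scope="session")
def mir145():
    return ms.MIR145_5P


@pytest.fixture(scope="session", autouse=True)
def _warm_dp_kernel(params, limits):
    # pay the numba JIT cost once, outside any timed assertion
    ms.hybridize_mfe(ms.rna("GGGG"), ms.rna("CCCC"), params, limits)
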