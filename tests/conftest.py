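import pytest

from oryzaroot.architecture import grow
from oryzaroot.params import default_dj123_params
from oryzaroot.uptake import system_uptake


@pytest.fixture(scope="session")
def params():
    return default_dj123_params()


@pytest.fixture(scope="session")
def system31(params):
    """One default architecture grown to the report day (31 = 28 DAE)."""
    return grow(params, seed=1, horizon=31)


@pytest.fixture(scope="session")
def uptake31(system31):
    """Uptake of the default architecture up to day 31."""
    return system_uptake(system31, at=31)
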