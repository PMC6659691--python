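import pytest

from mcsim import SimulationSettings
from mcsim.fixtures import (
    build_gpcr_fixture,
    build_ifng_fixture,
    build_inflammation_trio,
    build_mm_dc_pair,
)


@pytest.fixture(scope="session")
def settings():
    return SimulationSettings()


@pytest.fixture(scope="session")
def gpcr_net():
    return build_gpcr_fixture()


@pytest.fixture(scope="session")
def ifng_net():
    return build_ifng_fixture()


@pytest.fixture(scope="session")
def trio():
    """(cells, coupling, observed table) for the three-cell inflammation model."""
    return build_inflammation_trio()


@pytest.fixture(scope="session")
def mm_dc():
    return build_mm_dc_pair()
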