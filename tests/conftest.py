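import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tgisim import (
    CONTROL,
    DEMO_DELAY,
    DEMO_TRANSIT,
    PKParams,
    build_paper_regimens,
)


@pytest.fixture(scope="session")
def pk():
    return PKParams()  # half-life 6.9 d, unit concentration scale


@pytest.fixture(scope="session")
def library():
    return build_paper_regimens()


@pytest.fixture(scope="session")
def grid50():
    return np.linspace(0.0, 50.0, 501)


@pytest.fixture(scope="session")
def demo_transit():
    return DEMO_TRANSIT


@pytest.fixture(scope="session")
def demo_delay():
    return DEMO_DELAY


@pytest.fixture(scope="session")
def control():
    return CONTROL
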