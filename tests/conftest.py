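import pytest
from hypothesis import HealthCheck, settings

import molkmc as mk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def methane():
    return mk.build_alkane(1)


@pytest.fixture(scope="session")
def ethane():
    return mk.build_alkane(2)


@pytest.fixture(scope="session")
def octane():
    return mk.build_alkane(8)


@pytest.fixture(scope="session")
def octyl_radical():
    return mk.build_alkyl_radical(8, 0)


@pytest.fixture(scope="session")
def propyl_radical():
    return mk.build_alkyl_radical(3, 0)


@pytest.fixture(scope="session")
def dipeptide_water():
    return mk.build_dipeptide_with_water()


@pytest.fixture(scope="session")
def thymine_pair():
    return mk.build_thymine_pair()
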