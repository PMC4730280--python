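import pytest

from sodsplice import simulate as sim


@pytest.fixture(scope="session")
def cuzn():
    return sim.cu_zn_sod1_fixture()


@pytest.fixture(scope="session")
def mn1():
    return sim.mn_sod1_fixture()


@pytest.fixture(scope="session")
def mn2():
    return sim.mn_sod2_fixture()


@pytest.fixture(scope="session")
def fixtures(cuzn, mn1, mn2):
    return [cuzn, mn1, mn2]


@pytest.fixture(scope="session")
def profiles():
    return sim.default_profiles()
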