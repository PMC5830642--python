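import pytest

from symobs import fixture


@pytest.fixture(scope="session")
def goldbeter():
    return fixture("goldbeter5d")


@pytest.fixture(scope="session")
def rayleigh_benard():
    return fixture("rayleigh_benard9d")


@pytest.fixture(scope="session")
def dna():
    return fixture("dna13d")
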