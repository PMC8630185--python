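import pytest

from hdbiocompat import OperatingConditions, get_membrane


@pytest.fixture(scope="session")
def cta():
    return get_membrane("CTA")


@pytest.fixture(scope="session")
def paes():
    return get_membrane("PAES-PVP")


@pytest.fixture(scope="session")
def incubation():
    """Static in-vitro incubation: no flow, 30 min contact."""
    return OperatingConditions(Qb=0, t=30)
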