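import pytest

from radioyield import (
    StoppingModel,
    calibrated_toy_xs,
    havar,
    tellurium_dioxide,
    aluminum,
)


@pytest.fixture(scope="session")
def model():
    return StoppingModel()


@pytest.fixture(scope="session")
def teo2():
    return tellurium_dioxide()


@pytest.fixture(scope="session")
def havar_foil():
    return havar()


@pytest.fixture(scope="session")
def al():
    return aluminum()


@pytest.fixture(scope="session")
def toy_xs():
    return calibrated_toy_xs()
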