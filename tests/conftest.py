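import pytest

from gsmforge.synth import ToyModelSpec, default_medium, make_toy_model


@pytest.fixture(scope="session")
def toy():
    """Default toy reference model plus its planted truth."""
    return make_toy_model(ToyModelSpec())


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def glucose_medium():
    return default_medium()
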