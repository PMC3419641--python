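import pytest

from sdds import load_fixture


@pytest.fixture(scope="session")
def example():
    """Two-variable Boolean worked example."""
    return load_fixture("example_2_1_1")


@pytest.fixture(scope="session")
def p53():
    return load_fixture("p53_mdm2")


@pytest.fixture(scope="session")
def lam():
    return load_fixture("phage_lambda")
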