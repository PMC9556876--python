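import pytest

from pfpgo import generate_world


@pytest.fixture(scope="session")
def world():
    """The default synthetic world used across integration-level tests."""
    return generate_world(seed=1)
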