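import pytest

from cdekit import fixtures as fx


@pytest.fixture(scope="session")
def reg():
    """The worked-example registry (session-scoped; treat as read-only)."""
    return fx.example_registry()


@pytest.fixture()
def fresh_reg():
    """A private registry copy for tests that mutate."""
    return fx.example_registry()
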