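import numpy as np
import pytest

from askone.instruments import MChatKey


@pytest.fixture(scope="session")
def risk_if_yes_key() -> MChatKey:
    """Synthetic key where answering 'yes' (1) indicates risk on every item."""
    return MChatKey(tuple([True] * 20))


@pytest.fixture(scope="session")
def default_key() -> MChatKey:
    return MChatKey.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260401)
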