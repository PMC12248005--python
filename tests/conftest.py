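import copy

import pytest

from netglyph import generate_layout, tca_fixture
from netglyph.examples import tca_pipeline


@pytest.fixture(scope="session")
def tca_network():
    return tca_fixture()


@pytest.fixture()
def tca_layout(tca_network):
    return generate_layout(tca_network, (4500, 5000))


@pytest.fixture(scope="session")
def _tca_handle_session():
    """The full TCA worked example, run once per session (read-only)."""
    return tca_pipeline(seed=0)


@pytest.fixture()
def tca_handle(_tca_handle_session):
    """Deep copy so individual tests may mutate freely."""
    return copy.deepcopy(_tca_handle_session)
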