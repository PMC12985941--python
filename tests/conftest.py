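import pytest

from akglyc.parameters import load_params
from akglyc.steady_state import characteristic


@pytest.fixture(scope="session")
def ery():
    return load_params("erythrocyte")


@pytest.fixture(scope="session")
def muscle():
    return load_params("muscle")


@pytest.fixture(scope="session")
def ery_curve(ery):
    """Erythrocyte glycolysis characteristic on the default grid, shared
    across tests (it is deterministic and moderately expensive)."""
    return characteristic(ery)
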