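import numpy as np
import pytest

from phosevol.synthetic_orthologs import build_orthologs


@pytest.fixture(scope="session")
def orthologs():
    """Synthetic stand-in ortholog records and their alignment."""
    return build_orthologs()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
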