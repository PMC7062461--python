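import numpy as np
import pytest

from goku.core_io import DifGrammar
from goku.simulate import SimConfig


@pytest.fixture(scope="session")
def grammar() -> DifGrammar:
    return DifGrammar()


@pytest.fixture()
def small_cfg() -> SimConfig:
    """Compact host for fast end-to-end cycles; phage architecture unchanged."""
    return SimConfig(seed=11, host_len=20_000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(11)
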