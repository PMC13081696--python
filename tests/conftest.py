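import numpy as np
import pytest

from cerebmeg import FixtureConfig, make_head_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """Coarse head fixture (subdivision 3) shared across tests."""
    cfg = FixtureConfig(scalp_subdivision=3, source_subdivision=3)
    return make_head_fixture(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
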