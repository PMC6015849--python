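import numpy as np
import pytest

from nichetime import synthdata


@pytest.fixture(scope="session")
def fixture_table():
    """The deterministic worked-example species table."""
    return synthdata.paper_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20180744)


@pytest.fixture(scope="session")
def small_tree():
    """A fixed 6-tip ultrametric tree used by several oracle tests."""
    return synthdata.simulate_yule(6, 1.0, seed=42, normalize_height=True)
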