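import numpy as np
import pytest

import phylogm as pg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """8 tips x 12 points with allometric (0.30) and integration (0.20) truth."""
    return pg.make_dataset("tiny", seed=7)


@pytest.fixture(scope="session")
def tree50():
    return pg.simulate_tree(50, seed=42)


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures") / "tiny"
    pg.make_fixture("tiny", out, seed=7)
    return out
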