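import numpy as np
import pytest

from carveflux import carve
from carveflux.fixtures import ToySpec, make_toy_universal, two_condition_fixture


@pytest.fixture(scope="session")
def toy_model():
    """Toy universal model: 3-step backbone + full-span branch (7 reactions)."""
    return make_toy_universal(ToySpec(n_linear=3, n_branches=1, seed=0), endpoints=[(0, 3)])


@pytest.fixture(scope="session")
def chain_model():
    """Pure linear chain (no branch): every reaction carries the same flux."""
    return make_toy_universal(ToySpec(n_linear=3, n_branches=0, seed=0), endpoints=[])


@pytest.fixture(scope="session")
def fixture_pair():
    """(universal model, synthetic counts, expressed-per-condition truth)."""
    return two_condition_fixture(seed=0)


@pytest.fixture(scope="session")
def carved_pair(fixture_pair):
    """Carved models for both conditions of the ground-truth fixture."""
    model, _, expressed = fixture_pair
    out = {}
    for cond in ("A", "B"):
        scores = carve.score_reactions(model, expressed[cond])
        out[cond] = carve.carve(model, scores)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
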