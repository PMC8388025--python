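import pytest

from strainbench import fixtures as fx
from strainbench.model import apply_conditions


@pytest.fixture
def toy1():
    return fx.toy_model()


@pytest.fixture
def toy1_view(toy1):
    return apply_conditions(toy1)


@pytest.fixture
def toyreg():
    return fx.toy_regulatory()


@pytest.fixture
def toy_enz():
    return fx.toy_enzymatic()


@pytest.fixture(scope="session")
def random_models():
    """Seeded random pathway models of varying size (<= 10 reactions each)."""
    return [
        fx.random_model(n_linear_pathways=1 + seed % 3, seed=seed)
        for seed in range(20)
    ]
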