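import numpy as np
import pytest

from pcronet import ERRNParams, Graph, PCROConfig


@pytest.fixture
def hand_graph() -> Graph:
    """Six nodes, edges {0-1, 0-2, 0-3, 1-2, 4-5}: degrees [3,2,2,1,1,1],
    average degree 10/6; with k1=1, k2=avg the candidates are {3,4,5}."""
    return Graph(6, frozenset({(0, 1), (0, 2), (0, 3), (1, 2), (4, 5)}))


@pytest.fixture
def default_errn() -> ERRNParams:
    return ERRNParams(100, 0.05)


@pytest.fixture
def default_config() -> PCROConfig:
    return PCROConfig(p_pcro=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
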