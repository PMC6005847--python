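import numpy as np
import pytest

from neuroergm import Network, florentine_fixture


@pytest.fixture(scope="session")
def triangle():
    return Network.from_edges("abc", [("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture(scope="session")
def path3():
    return Network.from_edges("abc", [("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def k4():
    labels = "abcd"
    edges = [(u, v) for i, u in enumerate(labels) for v in labels[i + 1:]]
    return Network.from_edges(labels, edges)


@pytest.fixture(scope="session")
def florentine():
    return florentine_fixture()


def make_random_network(seed: int, n: int, p: float = 0.5) -> Network:
    rng = np.random.default_rng(seed)
    a = np.triu(rng.random((n, n)) < p, 1)
    return Network([f"n{i}" for i in range(n)], a | a.T)
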