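import numpy as np
import pytest

from pinabc import UndirectedGraph


def random_graph(n: int, p: float, rng: np.random.Generator) -> UndirectedGraph:
    """Erdos-Renyi-style test graph (test helper only)."""
    edges = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    }
    return UndirectedGraph(n, frozenset(edges))


@pytest.fixture
def rng():
    return np.random.default_rng(20120220)


@pytest.fixture
def triangle():
    return UndirectedGraph(3, frozenset({(0, 1), (1, 2), (0, 2)}))


@pytest.fixture
def path3():
    return UndirectedGraph(3, frozenset({(0, 1), (1, 2)}))
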