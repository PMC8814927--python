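import numpy as np
import pytest

from dcmflearn import collection_from_arrays
from dcmflearn.gra import Graph


@pytest.fixture()
def two_view_collection():
    """X1: e1 x e2 (4x3), X2: e1 x e3 (4x5); values deterministic."""
    rng = np.random.default_rng(42)
    x1 = rng.standard_normal((4, 3))
    x2 = rng.standard_normal((4, 5))
    return collection_from_arrays(
        {"X1": ("e1", "e2", x1), "X2": ("e1", "e3", x2)}
    )


@pytest.fixture()
def triangle_graph():
    return Graph.from_edges(
        [("a", "b"), ("b", "c"), ("c", "a")],
        {"a": "t", "b": "t", "c": "t"},
    )


def random_graph(rng, n, density=0.3, node_type="t"):
    nodes = {f"n{i}": node_type for i in range(n)}
    edges = [
        (f"n{i}", f"n{j}")
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < density
    ]
    return Graph.from_edges(edges, nodes)
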