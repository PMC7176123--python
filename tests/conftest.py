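import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cvdmap.spatial_graph import AdjacencyGraph, lattice_graph

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=50,
)
settings.load_profile("ci")


@pytest.fixture
def path3() -> AdjacencyGraph:
    """Path graph 1 - 2 - 3."""
    return AdjacencyGraph(n_areas=3, neighbours=[[1], [0, 2], [1]])


@pytest.fixture
def grid33() -> AdjacencyGraph:
    return lattice_graph(3, 3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def moran_i(values: np.ndarray, graph: AdjacencyGraph) -> float:
    """Moran's I with binary contiguity weights (test helper)."""
    x = np.asarray(values, dtype=float)
    xc = x - x.mean()
    num = sum(xc[j] * xc[l] for j, nbrs in enumerate(graph.neighbours) for l in nbrs)
    w_sum = sum(len(n) for n in graph.neighbours)
    return float(len(x) / w_sum * num / np.sum(xc**2))
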