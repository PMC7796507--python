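import numpy as np
import pytest

from jointmap.areal_graph import DistrictGraph, build_lattice_graph


@pytest.fixture(scope="session")
def path3() -> DistrictGraph:
    """Path graph A - B - C."""
    return DistrictGraph(("A", "B", "C"), ((0, 1), (1, 2)))


@pytest.fixture(scope="session")
def lattice52() -> DistrictGraph:
    return build_lattice_graph(4, 13)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 12) -> DistrictGraph:
    """Random connected graph: spanning tree plus random extra edges."""
    J = int(rng.integers(2, max_nodes + 1))
    ids = tuple(f"n{k:02d}" for k in range(J))
    edges = set()
    for k in range(1, J):
        edges.add((int(rng.integers(0, k)), k))
    n_extra = int(rng.integers(0, J))
    for _ in range(n_extra):
        a, b = rng.choice(J, size=2, replace=False)
        edges.add((min(int(a), int(b)), max(int(a), int(b))))
    return DistrictGraph(ids, tuple(sorted(edges)))
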