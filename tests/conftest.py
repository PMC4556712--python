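import numpy as np
import pytest

from ggmbench import NetworkTopology, build_ggm, finalize_connected, generate_random


@pytest.fixture(scope="session")
def small_er_topology():
    """Connected ER topology, 30 nodes / 60 edges."""
    return finalize_connected(generate_random(30, count=60, seed=42))


@pytest.fixture(scope="session")
def small_ggm(small_er_topology):
    return build_ggm(small_er_topology, seed=7)


@pytest.fixture(scope="session")
def chain3_topology():
    """3-node chain: 1 - 2 - 3 (0-based edges (0,1), (1,2))."""
    return NetworkTopology(3, frozenset({(0, 1), (1, 2)}))


def random_tree(n: int, seed: int) -> NetworkTopology:
    """Uniform-ish random tree: attach each node to a random earlier node."""
    rng = np.random.default_rng(seed)
    edges = set()
    for j in range(1, n):
        i = int(rng.integers(0, j))
        edges.add((i, j))
    return NetworkTopology(n, frozenset(edges))
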