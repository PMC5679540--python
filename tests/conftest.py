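import importlib.resources

import numpy as np
import pytest

from hamnet.graph import Graph, read_edge_list, read_partition


def random_graph(rng: np.random.Generator, n: int | None = None,
                 p: float | None = None) -> Graph:
    """Seeded Erdos-Renyi graph with string node labels (may be disconnected
    and may contain isolated nodes)."""
    if n is None:
        n = int(rng.integers(2, 25))
    if p is None:
        p = float(rng.uniform(0.05, 0.6))
    g = Graph(nodes=(str(v) for v in range(n)))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < p
    for a, b in zip(iu[mask], ju[mask]):
        g.add_edge(str(a), str(b))
    return g


def random_connected_graph(rng, n=None, p=None) -> Graph:
    """Random graph made connected by chaining components together."""
    g = random_graph(rng, n, p)
    comps = g.components()
    for a, b in zip(comps, comps[1:]):
        g.add_edge(min(a), min(b))
    return g


@pytest.fixture(scope="session")
def karate_graph():
    path = importlib.resources.files("hamnet") / "data" / "karate.tsv"
    return read_edge_list(str(path))


@pytest.fixture(scope="session")
def karate_truth():
    path = importlib.resources.files("hamnet") / "data" / "karate_truth.tsv"
    return read_partition(str(path))
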