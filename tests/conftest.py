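import networkx as nx
import numpy as np
import pytest

from phytoscreen.fixtures import FixtureConfig, generate_fixture


def random_connected_graph(rng: np.random.Generator, n_max: int = 30) -> nx.Graph:
    """Small random connected graph with string node ids."""
    n = int(rng.integers(5, n_max + 1))
    p = float(rng.uniform(0.15, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    # stitch components together so distances are mostly finite
    comps = [sorted(c) for c in nx.connected_components(g)]
    for a, b in zip(comps, comps[1:]):
        g.add_edge(a[0], b[0])
    return nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})


@pytest.fixture(scope="session")
def small_fixture():
    """One compact synthetic study shared by read-only tests."""
    return generate_fixture(
        FixtureConfig(
            n_nodes=120,
            n_compounds=40,
            module_size=8,
            embedding_dim=24,
            seed=7,
        )
    )


@pytest.fixture
def path_graph():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g
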