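import networkx as nx
import numpy as np
import pytest

from netcombo.fixtures import FixtureSpec, generate_planted_fixture, generate_similarity_inputs


@pytest.fixture(scope="session")
def default_bundle():
    """One shared planted-module fixture (seed 1)."""
    return generate_planted_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def sim_inputs(default_bundle):
    return generate_similarity_inputs(default_bundle, effect=1.0)


@pytest.fixture
def path_graph():
    """A–B–C–D path."""
    return nx.path_graph(["A", "B", "C", "D"])


def random_graph_with_sets(rng: np.random.Generator, max_n: int = 12):
    """One random graph plus two random nonempty (possibly overlapping) sets."""
    n = int(rng.integers(4, max_n + 1))
    p = float(rng.uniform(0.15, 0.55))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
    nodes = sorted(g.nodes)
    ka = int(rng.integers(1, n))
    kb = int(rng.integers(1, n))
    a = set(rng.choice(nodes, size=ka, replace=False))
    b = set(rng.choice(nodes, size=kb, replace=False))
    return g, a, b
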