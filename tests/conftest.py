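import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from targetnet.synthetic_data import tiny_fixture


def random_graphs(n_graphs: int, max_nodes: int, seed: int = 0,
                  connected: bool = False):
    """Seeded stream of small Erdős–Rényi graphs with string node names."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_graphs:
        n = int(rng.integers(3, max_nodes + 1))
        p = float(rng.uniform(0.15, 0.75))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes()})
        if connected:
            if not nx.is_connected(g):
                continue
        out.append(g)
    return out


@pytest.fixture(scope="session")
def tiny():
    return tiny_fixture()


@pytest.fixture()
def path3():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g
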