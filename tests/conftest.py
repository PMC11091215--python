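from functools import lru_cache

import networkx as nx
import pytest

from fuchsheet import build_sheet, canonical_unit


@pytest.fixture(scope="session")
def sheet():
    """Memoised sheet builder: tests must not mutate the returned graphs."""

    @lru_cache(maxsize=None)
    def _build(m: int, n: int) -> nx.Graph:
        return build_sheet(m, n)

    return _build


@pytest.fixture(scope="session")
def unit():
    return canonical_unit()


@pytest.fixture(scope="session")
def random_graphs():
    """Fifty small connected-or-not simple graphs with fixed seeds."""
    graphs = []
    for k in range(50):
        g = nx.gnm_random_graph(4 + k % 8, 5 + (k * 3) % 12, seed=1000 + k)
        g.remove_nodes_from(list(nx.isolates(g)))  # indices need degree >= 1
        if g.number_of_edges() > 0:
            graphs.append(g)
    return graphs
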