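import sys
from itertools import combinations
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nims import AnatomicalNetwork


def net_from_edges(edges, extra_nodes=(), laterality=None):
    nodes = []
    seen = set()
    for a, b in edges:
        for n in (a, b):
            if n not in seen:
                seen.add(n)
                nodes.append(n)
    for n in extra_nodes:
        if n not in seen:
            seen.add(n)
            nodes.append(n)
    return AnatomicalNetwork(nodes=nodes, edges=edges, laterality=laterality)


def clique_edges(labels):
    return [(a, b) for a, b in combinations(labels, 2)]


@pytest.fixture
def triangle():
    return net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3():
    return net_from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def k6():
    return net_from_edges(clique_edges([f"v{i}" for i in range(6)]))


@pytest.fixture
def barbell():
    """Two 4-cliques joined by a single bridge edge a3-b0."""
    a = [f"a{i}" for i in range(4)]
    b = [f"b{i}" for i in range(4)]
    return net_from_edges(clique_edges(a) + clique_edges(b) + [("a3", "b0")])


@pytest.fixture
def two_triangles():
    return net_from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
    )


@pytest.fixture
def clique_plus_pendant():
    """4-clique on a0..a3 plus pendant p attached to a0."""
    a = [f"a{i}" for i in range(4)]
    return net_from_edges(clique_edges(a) + [("a0", "p")])
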