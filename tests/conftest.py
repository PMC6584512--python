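import pytest

from cismine.examples import (
    attributed_demo_graph,
    distance_array_demo_graph,
    enumeration_demo_graph,
    parent_chain_demo_graph,
)
from cismine.graph import Graph


@pytest.fixture(scope="session")
def demo_graph():
    """The 14-vertex distance-array demonstration graph."""
    return distance_array_demo_graph()


@pytest.fixture(scope="session")
def chain_graph():
    return parent_chain_demo_graph()


@pytest.fixture(scope="session")
def diamond_graph():
    return enumeration_demo_graph()


@pytest.fixture(scope="session")
def attributed_graph():
    return attributed_demo_graph()


def path_graph(n: int) -> Graph:
    return Graph.from_edges(
        [(f"v{i:05d}", f"v{i + 1:05d}") for i in range(n - 1)],
        extra_vertices=[f"v{i:05d}" for i in range(n)],
    )


def complete_graph(n: int) -> Graph:
    return Graph.from_edges(
        [(f"v{i:02d}", f"v{j:02d}") for i in range(n) for j in range(i + 1, n)],
        extra_vertices=[f"v{i:02d}" for i in range(n)],
    )


def star_graph(k: int) -> Graph:
    """Center 'c00' plus k leaves; the center label sorts first."""
    return Graph.from_edges(
        [("c00", f"l{i:02d}") for i in range(k)], extra_vertices=["c00"]
    )


def cycle_graph(n: int) -> Graph:
    return Graph.from_edges(
        [(f"v{i:02d}", f"v{(i + 1) % n:02d}") for i in range(n)]
    )
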