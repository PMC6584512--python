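"""Seeded generators for random and attributed graphs.

Two emulated settings:

* Erdős–Rényi-style ``G(n, p)`` topologies at a controlled edge density, the
  regime used for enumeration stress tests (e.g. 27 vertices at density 0.6);
* attributed graphs with *planted modules*: connected vertex groups that
  share a chosen number of feature dimensions on top of an independent
  Bernoulli background of noise bits, the regime the cohesive miner is meant
  to recover.

A single integer seed drives one generator instance; the topology and the
attribute noise consume deterministically split sub-streams, so changing the
attribute noise never perturbs the topology.  Identical model, identical
output — byte-identical once written with the writers in
:mod:`cismine.graph`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Sequence

import numpy as np

from .graph import AttributedGraph, Graph

__all__ = [
    "PlantedModel",
    "PlantedModule",
    "PlantedInstance",
    "er_graph",
    "planted_attributed_graph",
]


def _labels(n: int) -> list[str]:
    # zero-padded so lexicographic label order equals numeric order
    width = max(1, len(str(n - 1)))
    return [f"v{i:0{width}d}" for i in range(n)]


def er_graph(n: int, density: float, seed: int) -> Graph:
    """``G(n, p)``: each of the n(n-1)/2 vertex pairs is an edge
    independently with probability ``density``.  Deterministic under
    ``seed``; all n vertices are kept even when isolated."""
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {density}")
    rng = np.random.default_rng(seed)
    labels = _labels(n)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    draws = rng.random(len(pairs)) < density
    edges = [
        (labels[i], labels[j]) for (i, j), keep in zip(pairs, draws) if keep
    ]
    return Graph.from_edges(edges, extra_vertices=labels)


@dataclass(frozen=True)
class PlantedModel:
    """Parameters of the planted attributed-graph generator.

    Defaults describe a moderate discovery setting: a sparse interaction
    network (n=50 at density 0.08), d=13 binary annotations per vertex (the
    dimensionality of a multi-condition dysregulation profile), two planted
    modules of five vertices sharing four dimensions each, and a 5% chance
    for any background bit to be on.
    """

    n: int = 50
    density: float = 0.08
    d: int = 13
    modules: tuple[tuple[int, int], ...] = ((5, 4), (5, 4))
    background_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must be in [0, 1]")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be in [0, 1]")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        for size, shared in self.modules:
            if size < 1 or size > self.n:
                raise ValueError(f"module size {size} out of range for n={self.n}")
            if shared < 0 or shared > self.d:
                raise ValueError(f"shared-feature count {shared} exceeds d={self.d}")
        if sum(size for size, _ in self.modules) > self.n:
            raise ValueError("module sizes exceed the vertex count")


@dataclass(frozen=True)
class PlantedModule:
    """Ground truth for one planted module."""

    vertices: FrozenSet[int]
    dims: FrozenSet[int]


@dataclass(frozen=True)
class PlantedInstance:
    agraph: AttributedGraph
    modules: tuple[PlantedModule, ...]


def planted_attributed_graph(model: PlantedModel) -> PlantedInstance:
    """Draw one attributed graph from a :class:`PlantedModel`.

    Topology: ER background at ``model.density`` plus, per module, a random
    spanning tree over its (disjointly sampled) members so the module is
    guaranteed connected.  Attributes: every bit independently on at
    ``background_rate``, then each module's shared dimensions forced to 1
    for all its members.  Every planted module is therefore cohesive at
    ``s_min`` equal to its shared-feature count, by construction.
    """
    ss = np.random.SeedSequence(model.seed)
    topo_rng, attr_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    n, d = model.n, model.d
    labels = _labels(n)

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    draws = topo_rng.random(len(pairs)) < model.density
    edge_ids = {pair for pair, keep in zip(pairs, draws) if keep}

    total = sum(size for size, _ in model.modules)
    chosen = topo_rng.choice(n, size=total, replace=False)
    modules: list[PlantedModule] = []
    offset = 0
    for size, shared in model.modules:
        members = [int(v) for v in chosen[offset : offset + size]]
        offset += size
        # random spanning tree: connect each member to a random earlier one
        order = topo_rng.permutation(members)
        for k in range(1, len(order)):
            a = int(order[k])
            b = int(order[topo_rng.integers(0, k)])
            edge_ids.add((a, b) if a < b else (b, a))
        dims = topo_rng.choice(d, size=shared, replace=False) if shared else []
        modules.append(
            PlantedModule(frozenset(members), frozenset(int(j) for j in dims))
        )

    graph = Graph.from_edges(
        [(labels[i], labels[j]) for i, j in sorted(edge_ids)],
        extra_vertices=labels,
    )

    bits_matrix = attr_rng.random((n, d)) < model.background_rate
    for mod in modules:
        for v in mod.vertices:
            for j in mod.dims:
                bits_matrix[v, j] = True
    features = tuple(
        int(sum(1 << j for j in range(d) if bits_matrix[v, j])) for v in range(n)
    )
    agraph = AttributedGraph(
        graph=graph,
        d=d,
        features=features,
        feature_names=tuple(f"f{j:02d}" for j in range(d)),
    )
    return PlantedInstance(agraph=agraph, modules=tuple(modules))
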