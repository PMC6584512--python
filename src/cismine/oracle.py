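"""Independent brute-force references and closed-form counters.

Everything here exists to cross-check the reverse-search enumerator and the
cohesive miner on small instances, so none of it shares traversal code with
them: connectivity is decided by union-find (with a plain iterative
depth-first check as a second, structurally different opinion), and candidate
generation is the naive power-set sweep.  Size guards refuse inputs where the
exponential sweep would blow up.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import FrozenSet

from .graph import AttributedGraph, Graph

__all__ = [
    "OracleResult",
    "brute_force_cis",
    "brute_force_maximal_cohesive",
    "closed_form_count",
    "is_connected_union_find",
    "is_connected_dfs",
]

_MAX_N_CIS = 22
_MAX_N_COHESIVE = 16


@dataclass(frozen=True)
class OracleResult:
    sets: frozenset[FrozenSet[int]]
    count: int


def is_connected_union_find(graph: Graph, members: frozenset[int]) -> bool:
    """Union-find connectivity of the induced subgraph (primary routine)."""
    if not members:
        return False
    parent = {v: v for v in members}

    def find(v: int) -> int:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for v in members:
        for w in graph.adjacency[v]:
            if w > v and w in members:
                rv, rw = find(v), find(w)
                if rv != rw:
                    parent[rv] = rw
    root = find(next(iter(members)))
    return all(find(v) == root for v in members)


def is_connected_dfs(graph: Graph, members: frozenset[int]) -> bool:
    """Iterative DFS connectivity (independent second opinion)."""
    if not members:
        return False
    start = next(iter(members))
    seen = {start}
    todo = [start]
    while todo:
        v = todo.pop()
        for w in graph.adjacency[v]:
            if w in members and w not in seen:
                seen.add(w)
                todo.append(w)
    return len(seen) == len(members)


def brute_force_cis(graph: Graph) -> OracleResult:
    """All non-empty connected vertex sets by sweeping the power set."""
    n = graph.n
    if n > _MAX_N_CIS:
        raise ValueError(f"brute-force guard: n={n} > {_MAX_N_CIS}")
    found: list[FrozenSet[int]] = []
    vertices = range(n)
    for k in range(1, n + 1):
        for combo in combinations(vertices, k):
            members = frozenset(combo)
            if is_connected_union_find(graph, members):
                found.append(members)
    return OracleResult(sets=frozenset(found), count=len(found))


def brute_force_maximal_cohesive(agraph: AttributedGraph, s_min: int) -> OracleResult:
    """All maximal cohesive subgraphs by definition: connected cohesive sets
    with no connected cohesive one-vertex extension (which, by
    anti-monotonicity, rules out every larger cohesive superset too)."""
    g = agraph.graph
    n = g.n
    if n > _MAX_N_COHESIVE:
        raise ValueError(f"brute-force guard: n={n} > {_MAX_N_COHESIVE}")
    f = agraph.features
    full = (1 << agraph.d) - 1

    maximal: list[FrozenSet[int]] = []
    for k in range(1, n + 1):
        for combo in combinations(range(n), k):
            members = frozenset(combo)
            sig = full
            for v in members:
                sig &= f[v]
            if sig.bit_count() < s_min:
                continue
            if not is_connected_union_find(g, members):
                continue
            extendable = False
            for v in members:
                for w in g.adjacency[v]:
                    if w not in members and (sig & f[w]).bit_count() >= s_min:
                        extendable = True
                        break
                if extendable:
                    break
            if not extendable:
                maximal.append(members)
    return OracleResult(sets=frozenset(maximal), count=len(maximal))


def closed_form_count(family: str, size: int) -> int:
    """Closed-form connected-set counts for standard graph families.

    path: n(n+1)/2 (contiguous intervals); complete: 2^n - 1; star with a
    center plus ``size`` leaves: 2^size + size; cycle: n(n-1) + 1 (proper
    arcs plus the full cycle).
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if family == "path":
        return size * (size + 1) // 2
    if family == "complete":
        return 2**size - 1
    if family == "star":
        return 2**size + size
    if family == "cycle":
        if size < 3:
            raise ValueError("cycle needs size >= 3")
        return size * (size - 1) + 1
    raise ValueError(f"unknown family {family!r}")
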