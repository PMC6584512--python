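"""Reverse-search enumeration of all connected induced subgraphs.

Every connected vertex set ``U`` of an undirected graph is arranged in a
forest by a *parent* operation: delete the **utmost** vertex — the member with
the longest shortest-path distance to the **anchor** (the minimum-id member of
``U``) inside the induced subgraph ``G(U)``, ties broken toward the larger id.
Deleting the farthest vertex from any fixed source cannot disconnect a
connected graph, so the parent of a connected set is connected, and repeated
application reaches the empty set.  Inverting the parent operation gives the
child rule: a neighbor ``v`` of ``U`` extends ``U`` iff ``v > anchor(U)`` and
``(dist(v), v) > (dist(u), u)`` where ``u`` is the current utmost — i.e. new
members arrive in strictly increasing ``(distance, id)`` order.  A depth-first
walk over this implicit forest therefore visits every connected induced
subgraph exactly once, with per-step cost proportional to the maximum degree
and total state linear in the number of vertices.

The mutable search state (:class:`EnumState`) keeps seven linear arrays: the
member list ``U`` (insertion order), the valid-candidate list ``C``, distance
``D`` and parent ``P`` per vertex, a membership tag per vertex, and a
restoration stack holding invalidated candidates with the depth and candidate
index needed to put them back, bit-exactly, on backtrack.

Distances never need updating after first assignment: members enter in
non-decreasing distance order, so when ``w`` first becomes a candidate via its
parent ``p`` (``D[w] = D[p] + 1``), every later member has distance at least
``D[p]``, and no path through later members can be shorter.

Candidates ``w <= anchor`` are never admitted to ``C``: the child rule
requires ``v > anchor`` for every node under the current root, so filtering at
insertion time is equivalent to the rejection at validity-check time and
avoids re-checking them at every node.
"""

from __future__ import annotations

from typing import Callable, FrozenSet, Iterable, Iterator

from .graph import Graph

__all__ = [
    "UNSET",
    "UNSEEN",
    "IN_U",
    "IN_C",
    "INVALIDATED",
    "EnumState",
    "anchor",
    "utmost",
    "parent_of",
    "is_valid_child",
    "iter_connected_sets",
    "enumerate_cis",
    "count_cis",
]

UNSET = -1

# membership tags
UNSEEN = 0
IN_U = 1
IN_C = 2
INVALIDATED = 3


def anchor(U: Iterable[int]) -> int:
    """The anchor of a vertex set: its minimum vertex id."""
    try:
        return min(U)
    except ValueError:
        raise ValueError("anchor of an empty vertex set is undefined") from None


def _bfs_distances(graph: Graph, members: frozenset[int], source: int) -> dict[int, int]:
    """BFS distances from ``source`` inside the induced subgraph G(members)."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in graph.adjacency[u]:
                if w in members and w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def utmost(graph: Graph, U: Iterable[int]) -> int:
    """The utmost vertex of a connected set: the member maximizing
    ``(distance to anchor within G(U), id)``.

    Raises ``ValueError`` if ``U`` is empty or does not induce a connected
    subgraph.
    """
    members = frozenset(U)
    s = anchor(members)
    dist = _bfs_distances(graph, members, s)
    if len(dist) != len(members):
        raise ValueError("vertex set does not induce a connected subgraph")
    return max(members, key=lambda v: (dist[v], v))


def parent_of(graph: Graph, U: Iterable[int]) -> FrozenSet[int]:
    """The parent of a connected set: ``U`` minus its utmost vertex.

    Standalone BFS-based form, independent of :class:`EnumState`; the empty
    set (canonical root) is returned for singletons.
    """
    members = frozenset(U)
    return members - {utmost(graph, members)}


class EnumState:
    """Mutable reverse-search state over a fixed :class:`~cismine.graph.Graph`.

    Drive it with :meth:`begin_root`, :meth:`extend` / :meth:`backtrack`, and
    :meth:`end_root`.  After a full depth-first traversal the state is
    restored to all-sentinel values (checked by :meth:`is_clean`).

    Attributes (the seven linear arrays)
    ------------------------------------
    U : list of int
        Members in insertion order; ``U[0]`` is the anchor, ``U[-1]`` the
        utmost vertex.
    C : list of int
        Currently valid candidates, sorted by distance (ids mixed within one
        distance level); every entry is a valid child of the current node.
    D, P : list of int
        Distance to the anchor / parent vertex, ``UNSET`` when untouched.
    tag : list of int
        UNSEEN / IN_U / IN_C / INVALIDATED per vertex.
    invalid_stack : list of (vertex, depth, index)
        Candidates invalidated when the utmost key grew past them, with the
        ``len(U)`` at invalidation time and their original index in ``C``.
    """

    __slots__ = ("graph", "U", "C", "D", "P", "tag", "invalid_stack", "_frames")

    def __init__(self, graph: Graph) -> None:
        n = graph.n
        self.graph = graph
        self.U: list[int] = []
        self.C: list[int] = []
        self.D: list[int] = [UNSET] * n
        self.P: list[int] = [UNSET] * n
        self.tag: list[int] = [UNSEEN] * n
        self.invalid_stack: list[tuple[int, int, int]] = []
        self._frames: list[tuple[int, int]] = []

    # ------------------------------------------------------------------ #

    def is_clean(self) -> bool:
        """True when every array is back at its initial sentinel value."""
        return (
            not self.U
            and not self.C
            and not self.invalid_stack
            and not self._frames
            and all(d == UNSET for d in self.D)
            and all(p == UNSET for p in self.P)
            and all(t == UNSEEN for t in self.tag)
        )

    def snapshot(self) -> tuple:
        """A deep, comparable copy of the full state (for inverse checks)."""
        return (
            tuple(self.U),
            tuple(self.C),
            tuple(self.D),
            tuple(self.P),
            tuple(self.tag),
            tuple(self.invalid_stack),
            tuple(self._frames),
        )

    # ------------------------------------------------------------------ #

    def begin_root(self, r: int) -> None:
        """Start a traversal rooted at the singleton ``{r}``; ``r`` becomes
        the anchor and its admissible neighbors enter ``C``."""
        if self.U:
            raise ValueError("begin_root on a non-empty state")
        D, P, tag, C = self.D, self.P, self.tag, self.C
        self.U.append(r)
        D[r] = 0
        tag[r] = IN_U
        for w in self.graph.adjacency[r]:
            if w > r:
                D[w] = 1
                P[w] = r
                tag[w] = IN_C
                C.append(w)

    def end_root(self) -> None:
        """Tear down the root frame set up by :meth:`begin_root`."""
        if len(self.U) != 1:
            raise ValueError("end_root requires exactly the root in U")
        D, P, tag = self.D, self.P, self.tag
        while self.C:
            w = self.C.pop()
            D[w] = UNSET
            P[w] = UNSET
            tag[w] = UNSEEN
        r = self.U.pop()
        D[r] = UNSET
        tag[r] = UNSEEN

    # ------------------------------------------------------------------ #

    def is_valid_child(self, v: int) -> bool:
        """Child-validity test: ``v > anchor`` and ``(D[v], v)`` exceeds the
        utmost's ``(distance, id)`` key.  ``D[v]`` must already be assigned
        (``v`` adjacent to the current subgraph).  Degenerate cases: with no
        members any vertex is acceptable as a root; with one member the
        condition reduces to ``v > anchor``."""
        if self.tag[v] == IN_U:
            raise ValueError(f"vertex {v} is already a member")
        if not self.U:
            return True
        s = self.U[0]
        if v <= s:
            return False
        u = self.U[-1]
        dv, du = self.D[v], self.D[u]
        return dv > du or (dv == du and v > u)

    def extend(self, v: int) -> None:
        """Append valid candidate ``v`` to ``U`` (public, validated form)."""
        if self.tag[v] != IN_C:
            raise ValueError(f"vertex {v} is not a current valid candidate")
        if not self.is_valid_child(v):
            raise ValueError(f"vertex {v} is not a valid child of the current node")
        self._extend_at(self.C.index(v))

    def _extend_at(self, i: int) -> None:
        """Append candidate ``C[i]`` to ``U``; O(Δ) plus the invalidation scan.

        Order of effects (reversed exactly by :meth:`backtrack`): remove the
        candidate, append it to ``U``, move now-stale candidates (key below
        the new utmost's) to the restoration stack, then admit unseen
        neighbors at distance ``D[v] + 1``.
        """
        C, D, P, tag = self.C, self.D, self.P, self.tag
        v = C.pop(i)
        dv = D[v]
        s = self.U[0]
        self.U.append(v)
        tag[v] = IN_U
        depth = len(self.U)

        # C is sorted by distance, so stale entries live in the prefix with
        # D <= dv; within the D == dv block staleness is an id comparison.
        kill: list[int] = []
        for j, x in enumerate(C):
            dx = D[x]
            if dx > dv:
                break
            if dx < dv or x < v:
                kill.append(j)
        inv = self.invalid_stack
        for j in reversed(kill):
            x = C.pop(j)
            tag[x] = INVALIDATED
            inv.append((x, depth, j))

        for w in self.graph.adjacency[v]:
            if tag[w] == UNSEEN and w > s:
                D[w] = dv + 1
                P[w] = v
                tag[w] = IN_C
                C.append(w)
        self._frames.append((v, i))

    def backtrack(self) -> None:
        """Exact inverse of the matching extend; the state becomes
        bit-identical to what it was before that extend."""
        if len(self.U) <= 1:
            raise ValueError("backtrack past the root")
        v, i = self._frames.pop()
        C, D, P, tag = self.C, self.D, self.P, self.tag
        # neighbors admitted by v sit contiguously at the tail of C
        while C and P[C[-1]] == v:
            w = C.pop()
            D[w] = UNSET
            P[w] = UNSET
            tag[w] = UNSEEN
        # restore candidates invalidated at this depth to their original
        # indices (stack pops them in increasing-index order)
        depth = len(self.U)
        inv = self.invalid_stack
        while inv and inv[-1][1] == depth:
            x, _, j = inv.pop()
            C.insert(j, x)
            tag[x] = IN_C
        self.U.pop()
        tag[v] = IN_C
        C.insert(i, v)


def is_valid_child(state: EnumState, v: int) -> bool:
    """Module-level form of :meth:`EnumState.is_valid_child`."""
    return state.is_valid_child(v)


def _iter_states(graph: Graph, state: EnumState | None = None) -> Iterator[EnumState]:
    """Depth-first pre-order walk yielding the live state at every node.

    The yielded object is the single mutable state — inspect it, do not
    mutate it.  Abandoning the iterator mid-walk leaves the state mid-walk.
    """
    if state is None:
        state = EnumState(graph)
    if not state.is_clean():
        raise ValueError("traversal requires a clean state")
    for r in range(graph.n):
        state.begin_root(r)
        yield state
        stack = [0]
        while stack:
            i = stack[-1]
            if i < len(state.C):
                stack[-1] = i + 1
                state._extend_at(i)
                yield state
                stack.append(0)
            else:
                stack.pop()
                if stack:
                    state.backtrack()
        state.end_root()


def iter_connected_sets(graph: Graph) -> Iterator[FrozenSet[int]]:
    """Stream every connected vertex set of ``graph`` exactly once.

    Emission is pre-order depth-first: under root ``r`` exactly the connected
    sets whose minimum id is ``r`` appear, in deterministic order.  Memory
    stays linear in the vertex count regardless of how many sets exist, so
    the first solutions arrive without enumerating the rest.
    """
    for state in _iter_states(graph):
        yield frozenset(state.U)


def enumerate_cis(
    graph: Graph, visitor: Callable[[FrozenSet[int]], None] | None = None
) -> int:
    """Invoke ``visitor`` once per connected vertex set; return the total.

    A visitor exception aborts the enumeration and propagates.  With no
    visitor this is :func:`count_cis`.
    """
    if visitor is None:
        return count_cis(graph)
    total = 0
    for s in iter_connected_sets(graph):
        visitor(s)
        total += 1
    return total


def count_cis(graph: Graph) -> int:
    """Count connected vertex sets without materializing any of them."""
    state = EnumState(graph)
    total = 0
    for r in range(graph.n):
        state.begin_root(r)
        total += 1
        stack = [0]
        while stack:
            i = stack[-1]
            if i < len(state.C):
                stack[-1] = i + 1
                state._extend_at(i)
                total += 1
                stack.append(0)
            else:
                stack.pop()
                if stack:
                    state.backtrack()
        state.end_root()
    return total
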