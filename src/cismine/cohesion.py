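"""Mining all maximal cohesive subgraphs of a binary-attributed graph.

A feature dimension is *cohesive* for a vertex set ``U`` when every member
has it set; ``A(U)`` denotes the set of cohesive dimensions, here an int
bitset obtained by AND-ing member feature vectors (all-ones for the empty
set).  ``G(U)`` is *cohesive* when it is connected and ``|A(U)| >= s_min``,
and *maximal cohesive* when additionally no connected cohesive strict
superset exists.  Because the constraint is anti-monotone (a subset of a
cohesive set is cohesive) and supersets are connected through single-vertex
steps, maximality reduces to "no single graph neighbor keeps ``s_min``
cohesive dimensions".

The miner walks the reverse-search forest of connected sets restricted to
cohesive nodes and reports the nodes passing the maximality test.  Two sound
prunings shrink the walk without changing the result set:

* **covering sibling** — among the cohesive child extensions of a node,
  ordered by the child total order ``(distance-to-anchor, id)``, a candidate
  ``y`` whose extension signature is contained in that of an earlier kept
  sibling ``x`` spawns no maximal set (``x`` can always be re-added to any
  descendant of the ``y``-branch), so its subtree is skipped.  At level one
  (singleton roots) the same argument prunes a root ``v`` with an adjacent
  smaller-id vertex ``w`` whose features contain ``f(v)``.
* **parent-identical child** — if a child's signature equals its parent's,
  every later sibling is covered by that child, so the miner recurses into
  it and skips the rest of the candidate list.

Equal-signature ordered siblings cover each other; the earlier one survives,
which keeps the traversal deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, FrozenSet, Iterable, NamedTuple, Sequence

from .graph import AttributedGraph, CismineError
from .reverse_search import IN_U, EnumState

__all__ = [
    "MiningConfig",
    "CohesiveSubgraph",
    "PruneEvent",
    "signature",
    "support",
    "is_cohesive",
    "order_candidates",
    "prune_covered_siblings",
    "level_one_keep",
    "same_as_parent_cutoff",
    "is_maximal",
    "mine_maximal_cohesive",
    "format_result_line",
]


@dataclass(frozen=True)
class MiningConfig:
    """Mining parameters.

    s_min : minimum number of cohesive dimensions (0 allowed: every connected
        set qualifies and the maximal sets are the connected components).
    prune_covering_sibling / prune_same_as_parent / prune_level_one :
        individual switches for the prunings; results are identical for every
        on/off combination, only traversal size changes.
    """

    s_min: int
    prune_covering_sibling: bool = True
    prune_same_as_parent: bool = True
    prune_level_one: bool = True

    def __post_init__(self) -> None:
        if self.s_min < 0:
            raise CismineError("s_min must be non-negative")


@dataclass(frozen=True)
class CohesiveSubgraph:
    """One reported maximal cohesive subgraph."""

    members: FrozenSet[int]
    signature: int


class PruneEvent(NamedTuple):
    """A traversal event, for logging/inspection of the search.

    kind is one of ``"level_one"`` (root ``vertex`` pruned, ``witness`` its
    covering smaller neighbor), ``"covered_sibling"`` (candidate ``vertex``
    at node ``node`` covered by kept sibling ``witness``),
    ``"parent_identical"`` (child ``vertex`` of ``node`` repeats the parent
    signature; ``skipped`` are the later candidates cut), ``"report"``.
    """

    kind: str
    node: tuple[int, ...]
    vertex: int
    witness: int = -1
    skipped: tuple[int, ...] = ()


def signature(agraph: AttributedGraph, U: Iterable[int]) -> int:
    """``A(U)`` as a bitset: AND of member feature vectors, all-ones when
    ``U`` is empty."""
    sig = (1 << agraph.d) - 1
    for v in U:
        sig &= agraph.features[v]
    return sig


def support(sig: int) -> int:
    return sig.bit_count()


def is_cohesive(sig: int, config: MiningConfig) -> bool:
    """Does the signature keep at least ``s_min`` cohesive dimensions?"""
    return sig.bit_count() >= config.s_min


def order_candidates(state: EnumState, candidates: Sequence[int]) -> list[int]:
    """Sort candidates by the child total order ``(D[x], x)`` — ascending
    closeness to the anchor, ids breaking ties."""
    D = state.D
    return sorted(candidates, key=lambda x: (D[x], x))


def prune_covered_siblings(
    agraph: AttributedGraph, parent_sig: int, ordered: Sequence[int]
) -> list[bool]:
    """Keep flags for an ordered, all-cohesive candidate list.

    Candidate ``y`` is dropped iff some earlier *kept* candidate ``x``
    satisfies ``parent_sig & f(y) ⊆ parent_sig & f(x)`` (signature
    containment of the two sibling extensions).  Mutual containment keeps
    only the earlier sibling.
    """
    f = agraph.features
    keep: list[bool] = []
    kept_sigs: list[int] = []
    for y in ordered:
        sy = parent_sig & f[y]
        covered = any(sy & sx == sy for sx in kept_sigs)
        keep.append(not covered)
        if not covered:
            kept_sigs.append(sy)
    return keep


def level_one_keep(agraph: AttributedGraph, v: int) -> bool:
    """Is root ``v`` worth exploring?  False iff some neighbor ``w < v`` has
    ``f(v) ⊆ f(w)`` — any maximal set found under root ``v`` could then
    absorb ``w`` without losing a cohesive dimension, contradicting
    maximality."""
    fv = agraph.features[v]
    for w in agraph.graph.adjacency[v]:
        if w >= v:
            break
        if fv & agraph.features[w] == fv:
            return False
    return True


def _level_one_witness(agraph: AttributedGraph, v: int) -> int:
    fv = agraph.features[v]
    for w in agraph.graph.adjacency[v]:
        if w >= v:
            break
        if fv & agraph.features[w] == fv:
            return w
    return -1


def same_as_parent_cutoff(parent_sig: int, child_sig: int) -> bool:
    """True when the child keeps every cohesive dimension of its parent, so
    all of the child's later siblings can be skipped."""
    return child_sig == parent_sig


def is_maximal(
    agraph: AttributedGraph,
    U: Iterable[int],
    sig: int,
    config: MiningConfig,
) -> bool:
    """No graph neighbor of ``U`` — valid child, invalidated candidate, or
    pruned vertex, including ids below the anchor — keeps ``s_min`` cohesive
    dimensions when added.  By anti-monotonicity plus connectivity this
    single-vertex test equals global maximality."""
    members = set(U)
    s_min = config.s_min
    f = agraph.features
    adjacency = agraph.graph.adjacency
    for u in members:
        for w in adjacency[u]:
            if w not in members and (sig & f[w]).bit_count() >= s_min:
                return False
    return True


@dataclass
class _Frame:
    kept: list[int]
    idx: int
    sig: int
    cutoff: bool = False


def mine_maximal_cohesive(
    agraph: AttributedGraph,
    config: MiningConfig,
    on_event: Callable[[PruneEvent], None] | None = None,
) -> list[CohesiveSubgraph]:
    """All maximal cohesive subgraphs, each exactly once, in depth-first
    discovery order.

    Raises :class:`~cismine.graph.CismineError` when ``s_min`` exceeds the
    attribute dimension count.
    """
    if config.s_min > agraph.d:
        raise CismineError(
            f"S_min exceeds attribute dimension: s_min={config.s_min} > d={agraph.d}"
        )
    g = agraph.graph
    f = agraph.features
    s_min = config.s_min
    state = EnumState(g)
    results: list[CohesiveSubgraph] = []

    def emit(ev: PruneEvent) -> None:
        if on_event is not None:
            on_event(ev)

    def maximal_now(sig: int) -> bool:
        # in-traversal maximality: scan all graph neighbors of U via tags
        tag = state.tag
        for u in state.U:
            for w in g.adjacency[u]:
                if tag[w] != IN_U and (sig & f[w]).bit_count() >= s_min:
                    return False
        return True

    def children_of(sig: int) -> list[int]:
        cands = [v for v in state.C if (sig & f[v]).bit_count() >= s_min]
        ordered = order_candidates(state, cands)
        if config.prune_covering_sibling and len(ordered) > 1:
            keep = prune_covered_siblings(agraph, sig, ordered)
            kept = []
            kept_sigs: list[tuple[int, int]] = []
            for y, k in zip(ordered, keep):
                if k:
                    kept.append(y)
                    kept_sigs.append((y, sig & f[y]))
                else:
                    sy = sig & f[y]
                    witness = next(
                        x for x, sx in kept_sigs if sy & sx == sy
                    )
                    emit(
                        PruneEvent(
                            "covered_sibling", tuple(state.U), y, witness
                        )
                    )
            return kept
        return ordered

    for r in range(g.n):
        if f[r].bit_count() < s_min:
            continue
        if config.prune_level_one and not level_one_keep(agraph, r):
            emit(PruneEvent("level_one", (), r, _level_one_witness(agraph, r)))
            continue
        state.begin_root(r)
        root_sig = f[r]
        if maximal_now(root_sig):
            emit(PruneEvent("report", (r,), r))
            results.append(CohesiveSubgraph(frozenset((r,)), root_sig))
        frames = [_Frame(children_of(root_sig), 0, root_sig)]
        while frames:
            fr = frames[-1]
            if fr.cutoff or fr.idx >= len(fr.kept):
                frames.pop()
                if frames:
                    state.backtrack()
                continue
            v = fr.kept[fr.idx]
            fr.idx += 1
            state.extend(v)
            child_sig = fr.sig & f[v]
            if maximal_now(child_sig):
                emit(PruneEvent("report", tuple(state.U), v))
                results.append(CohesiveSubgraph(frozenset(state.U), child_sig))
            if config.prune_same_as_parent and same_as_parent_cutoff(fr.sig, child_sig):
                skipped = tuple(fr.kept[fr.idx:])
                emit(
                    PruneEvent(
                        "parent_identical", tuple(state.U[:-1]), v, skipped=skipped
                    )
                )
                fr.cutoff = True
            frames.append(_Frame(children_of(child_sig), 0, child_sig))
        state.end_root()
    return results


def format_result_line(agraph: AttributedGraph, result: CohesiveSubgraph) -> str:
    """``label<TAB>...<TAB>|<TAB>dim,dim,...`` — members ascending by id,
    cohesive dimension names sorted."""
    g = agraph.graph
    labels = [g.labels[i] for i in sorted(result.members)]
    dims = ",".join(sorted(agraph.dims_of(result.signature)))
    return "\t".join(labels) + "\t|\t" + dims
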