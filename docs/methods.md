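# Methods

## Problem

Given an undirected simple graph G = (V, E), a *connected vertex set* is a
subset U ⊆ V whose induced subgraph G(U) is connected. `cismine` enumerates
the family CIS(G) = { U | G(U) connected } exactly once per set, in a stream,
with auxiliary memory linear in |V|. On top of the enumeration it mines
binary-attributed graphs G = (V, E, f), f : V → {0,1}^d, for all *maximal
cohesive subgraphs*: connected sets whose members share at least S_min
feature dimensions and that have no connected superset still sharing S_min
dimensions. The motivating use is module discovery in molecular interaction
networks where each vertex carries a binary profile (e.g. dysregulation
across conditions), but nothing in the implementation is specific to that
domain.

## Reverse search with a shortest-path parent rule

All connected sets are arranged in a forest by a parent operation. Fix the
**anchor** of U as its minimum-id member. The **utmost** vertex is the member
maximizing the pair (shortest-path distance to the anchor inside G(U), id).
Removing the farthest vertex from a fixed source cannot disconnect a
connected graph — any vertex separated by the removal would have been
farther — so "delete the utmost vertex" maps every connected set to a
connected set one smaller, and repeated application reaches the empty set.

Inverting this map gives the child rule: a neighbor v of U extends U into a
tree child exactly when v > anchor(U) and (dist(v), v) exceeds the utmost's
(dist, id) pair. Members therefore arrive in strictly increasing
(distance, id) order along any root-to-node path. A depth-first traversal of
the implicit forest — one root per vertex, in ascending id order — visits
every connected set exactly once, emitting each node in pre-order, which
makes the output stream deterministic.

Vertex order: input labels are sorted ascending at load time and mapped to
dense ids; every comparison afterwards is an integer comparison. Any fixed
total order works; sorting makes runs reproducible across input orderings.

### State and complexity

The mutable search state is seven linear arrays: the member list U
(insertion order; U[0] the anchor, U[-1] the utmost), the valid-candidate
list C, per-vertex distance D and parent P, a per-vertex membership tag, and
a restoration stack holding, per invalidated candidate, the |U| at
invalidation and its original index in C. Extension appends the candidate,
moves stale candidates (pairs below the new utmost's) to the restoration
stack, and admits unseen neighbors at distance D[v] + 1. Backtracking
reverses those effects exactly — admitted neighbors sit contiguously at the
tail of C, invalidated candidates are re-inserted at their recorded indices,
and the moved vertex returns to its prior C position — so the pre-extension
state is restored bit-for-bit (asserted in tests by snapshot equality, and by
an all-sentinel check after full traversals). Checking a candidate costs
O(1); building a child's state costs O(Δ) plus the invalidation scan, Δ the
maximum degree; total space is O(|V|).

Two deliberate deviations from the most literal formulation, both behavior-
preserving:

* **Admission filter.** Neighbors w ≤ anchor are never admitted to C.
  Every child under the current root must satisfy v > anchor, so rejecting
  at admission time is equivalent to rejecting at validity-check time and
  avoids re-scanning such vertices at every node.
* **Fixed distances.** D[w] is set once, at first admission, to
  D[parent] + 1 and never updated. Correctness follows from the monotone
  arrival order: when w is admitted, every later member has distance at
  least D[parent], so no later member can offer a shorter path to the
  anchor. Tests recompute BFS distances at every node of small random
  traversals to confirm.

The candidate list stays sorted by distance (admissions use the current
maximum distance plus one), so the invalidation scan stops at the first
entry past the new utmost's distance.

The traversal is iterative (an explicit index stack), because the DFS depth
is bounded only by |V| and must survive path-like graphs with 10^4 vertices,
beyond default interpreter recursion limits.

## Cohesive mining

A(U), the set of cohesive dimensions, is the bitwise AND of member feature
vectors (all-ones for the empty set), maintained incrementally along the
search path. Cohesion — |A(U)| ≥ S_min — is anti-monotone, so the ancestors
of any cohesive node are cohesive and restricting the traversal to cohesive
nodes loses nothing. Maximality reduces to a local test: U is maximal iff no
single graph neighbor w (valid candidate, invalidated, pruned, or below the
anchor — the candidate array alone is *not* sufficient once pruning removes
vertices) keeps |A(U) ∧ f(w)| ≥ S_min, because any connected strict superset
is reachable one adjacent vertex at a time and cohesion only shrinks.

Two prunings cut subtrees that provably contain no maximal set:

* **Covering sibling.** Order the cohesive candidate extensions of a node by
  (distance, id) — the same total order the child rule uses. If an earlier
  kept sibling x satisfies A(U ∪ {y}) ⊆ A(U ∪ {x}), every descendant of the
  y-branch can absorb x without losing a cohesive dimension (x stays
  adjacent and is never a valid extension inside that branch, so nothing
  there is maximal): the y-subtree is skipped. Checking against *kept*
  siblings only is enough — containment is transitive. Two ordered siblings
  with identical signatures cover each other; the earlier one survives,
  keeping the traversal deterministic. The check is pairwise, O(k²) in the
  candidate count k, acceptable since k ≤ Δ.
* **Level-one special case.** For singleton roots the same argument applies
  against *any adjacent smaller-id vertex* w with f(v) ⊆ f(w): every set
  found under root v excludes w (roots own the sets whose minimum is the
  root) yet could absorb it, so root v is skipped entirely. When two
  adjacent vertices have identical feature vectors the smaller id survives.
* **Parent-identical child.** If a child's signature equals its parent's,
  every later sibling is covered by that child; the miner recurses into it
  and skips the rest of the candidate list. Logically a special case of the
  covering rule, kept separate because it avoids the pairwise containment
  scan.

All three prunings are switchable; the result set is identical for every
on/off combination (tested exhaustively against a brute-force reference on
~100 seeded instances). S_min = 0 degenerates gracefully: every connected
set is cohesive and exactly the connected components are maximal.

## Tunable parameters

| Parameter | Meaning | Default | Notes |
|---|---|---|---|
| `s_min` | minimum shared dimensions for cohesion | required | 0 ≤ s_min ≤ d; s_min > d is an error |
| pruning flags | enable each pruning | all on | correctness never depends on them |
| `PlantedModel.n` | synthetic vertex count | 50 | moderate network scale for tests |
| `PlantedModel.density` | ER edge probability | 0.08 | sparse, interaction-network-like |
| `PlantedModel.d` | attribute dimensions | 13 | the dimensionality of a multi-condition binary profile |
| `PlantedModel.modules` | (size, shared-dims) per planted module | ((5,4),(5,4)) | disjointly sampled memberships |
| `PlantedModel.background_rate` | P(noise bit = 1) | 0.05 | 0 makes recovery exact |
| `PlantedModel.seed` | generator seed | 0 | one seed; topology and attribute noise use split sub-streams |

## Synthetic data: what it emulates, what it does not

`er_graph` draws each vertex pair independently (Erdős–Rényi G(n, p)) — the
standard stress regime for enumeration, where the connected-set count grows
toward 2^n as density rises. `planted_attributed_graph` overlays (a) a
random spanning tree per planted module, guaranteeing the module is
connected, and (b) forced 1-bits in the module's shared dimensions, over an
independent Bernoulli bit background. Every planted module is therefore
cohesive at S_min equal to its shared-dimension count, by construction, and
with a zero background rate the planted modules are exactly the maximal
cohesive sets.

What this does not emulate: degree heterogeneity (hubs), clustering, and
correlated annotations of real interaction networks, and overlap between
modules. Passing recovery tests therefore demonstrates algorithmic
correctness and recoverability under clean planted structure, not expected
discovery rates on real biological networks, where background cohesion can
merge or extend modules (the noisy-background tests accordingly assert
containment of each planted module in some reported set, not equality).

## Numerical and degenerate-input choices

* Feature vectors and signatures are arbitrary-precision integer bitsets;
  AND and popcount are exact, so there are no tolerances anywhere.
* Ties in the utmost choice go to the larger id; ties between
  equal-signature siblings go to the earlier (closer, then smaller-id)
  sibling; both are forced by the orders above, no freedom taken.
* Disconnected input graphs are accepted; each component's sets appear under
  its own roots. Isolated vertices (declared via a `# vertices:` directive)
  yield exactly their singleton set.
* Self-loops and duplicate/reversed edges are dropped with a warning;
  a data line with fewer than two tokens is an error naming the line.
* The empty vertex set is the canonical forest root and is never emitted.

## Test scales

Property and acceptance tests run the exact brute-force reference up to
n = 12 (mining up to d = 6), closed-form count checks up to size 20,
complete enumeration of a 20-vertex density-0.6 random graph (~10^6 sets),
and streaming checks on 27- and 1000-vertex graphs; these sizes keep the
full suite under a minute while exercising every code path, including search
depths of 10^4 on path graphs.

## Known limitations

* Pure-Python inner loop: throughput is roughly 5×10^5 sets/second;
  exhaustive enumeration of graphs much beyond 25 dense vertices is
  better consumed as a stream than materialized.
* Binary attributes only; real-valued similarity constraints are out of
  scope.
* No parallel traversal; the forest decomposes naturally by root, so
  coarse-grained parallelism is possible but not implemented.
* The covering-sibling check is quadratic in the per-node candidate count,
  which is fine for bounded-degree graphs but could matter on dense graphs
  with thousands of neighbors.
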