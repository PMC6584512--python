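# cismine

Exact, streaming enumeration of **all connected induced subgraphs** of an
undirected graph, and mining of **all maximal cohesive subgraphs** of a
binary-attributed graph. The intended audience is anyone who needs the
complete family of connected vertex sets (or its constrained, maximal
members) rather than a heuristic sample — e.g. module discovery in molecular
interaction networks where each gene/protein carries a binary annotation
profile and a module is a connected set of vertices sharing many
annotations.

## The algorithm

Every connected vertex set U ⊆ V is arranged in a forest by a *parent*
operation: delete the **utmost** vertex — the member with the largest
(shortest-path distance to the **anchor**, id) pair, where the anchor is the
minimum-id member and distances are measured inside the induced subgraph
G(U). Deleting the farthest vertex from a fixed source cannot disconnect a
connected graph, so the parent of a connected set is connected. Inverting
the rule gives the children: neighbor v extends U iff v > anchor(U) and
(dist(v), v) exceeds the utmost's pair. Depth-first traversal of this
implicit forest emits every connected set exactly once, with O(Δ) work per
extension and O(|V|) total state (seven linear arrays), i.e. solutions
stream out with linear delay and flat memory.

For an attributed graph G = (V, E, f), f : V → {0,1}^d, the set of cohesive
dimensions A(U) = { j | f(v)[j] = 1 ∀v ∈ U } is maintained incrementally as
a bitset, and G(U) is *cohesive* when |A(U)| ≥ S_min — an anti-monotone
constraint, so the traversal restricted to cohesive nodes is still complete.
A node is reported iff no graph neighbor keeps S_min dimensions. Two sound
prunings (skip a sibling whose extension signature is contained in an
earlier sibling's; stop scanning siblings after a child that keeps its
parent's entire signature) cut the search without changing the result —
verified exhaustively against a brute-force reference.

See `docs/methods.md` for the full account, including the correctness
arguments and the synthetic-data model.

## Worked example

A six-vertex graph with five binary annotations per vertex:

```sh
$ cat demo.edges
A B
A F
A H
B C
B G
F H

$ cat demo.attrs        # feature-list dialect; a 0/1 matrix also works
A	d0,d1,d2,d3
B	d0,d1,d3,d4
C	d0,d1,d3
F	d0,d1,d4
G	d0,d2,d3
H	d0,d1,d3

$ cismine count demo.edges
29
```

29 is the number of connected vertex sets: every one of the 2^6 − 1 = 63
non-empty subsets that happens to induce a connected subgraph, counted
without materializing any of them. Enumerating streams them instead, one
tab-separated line per set, in deterministic depth-first order:

```sh
$ cismine enumerate demo.edges | head -5
A
A	B
A	B	F
A	B	F	H
A	B	C	F	H
```

Mining with a threshold of two shared annotations:

```sh
$ cismine mine demo.edges --attributes demo.attrs --smin 2
A	B	C	F	H	|	d0,d1
A	B	C	G	H	|	d0,d3
```

Exactly two maximal cohesive subgraphs exist: {A,B,C,F,H}, whose members all
carry d0 and d1, and {A,B,C,G,H}, whose members all carry d0 and d3. Each
line lists the members, then the shared dimensions after the `|`. Neither
set can be grown: the only vertex outside each keeps at most one of its
shared dimensions. Every connected subset of these sets shares at least as
many dimensions, which is why only the two maximal ones are reported.

The same six-vertex instance is built into the library as
`cismine.examples.attributed_demo_graph()`; `cismine simulate` generates
larger planted-module benchmarks (edge list + attribute table + provenance
YAML) from a seed.

As a library:

```python
from cismine import read_edge_list, iter_connected_sets, count_cis

with open("demo.edges") as fh:
    graph = read_edge_list(fh)
for s in iter_connected_sets(graph):   # frozensets of vertex ids, streamed
    ...
```

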