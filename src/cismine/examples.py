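"""Small built-in demonstration graphs used in docs and tests.

These are synthetic reconstructions assembled for this package: compact
instances on which every step of the enumeration and the mining can be
worked through by hand.
"""

from __future__ import annotations

from .graph import AttributedGraph, Graph

__all__ = [
    "distance_array_demo_graph",
    "DEMO_SUBSET_LABELS",
    "parent_chain_demo_graph",
    "enumeration_demo_graph",
    "attributed_demo_graph",
]

# 14 vertices, 22 edges.  With U = {02..05, 07, 09} the distance-array state
# is fully instructive: anchor 02, utmost 09 at distance 3, candidates
# discovered in the order 03, 05, 04, 06, 07, 09, 10, 08, 14, and extending
# with vertex 10 admits 11 and 12 at distance 4 with parent 10.  Vertex 13
# touches none of those members.
_DEMO_EDGES = [
    ("01", "02"),
    ("01", "06"),
    ("02", "03"),
    ("02", "05"),
    ("03", "04"),
    ("03", "06"),
    ("04", "05"),
    ("04", "07"),
    ("04", "09"),
    ("04", "10"),
    ("05", "06"),
    ("07", "08"),
    ("07", "09"),
    ("08", "09"),
    ("08", "14"),
    ("09", "14"),
    ("10", "11"),
    ("10", "12"),
    ("11", "12"),
    ("11", "13"),
    ("12", "13"),
    ("13", "14"),
]

#: the worked-example member set, as labels (ids are label index, i.e. k-1)
DEMO_SUBSET_LABELS = ("02", "03", "04", "05", "07", "09")


def distance_array_demo_graph() -> Graph:
    """The 14-vertex, 22-edge distance-array demonstration graph.

    Labels are zero-padded numerals "01".."14" so lexicographic order equals
    numeric order and vertex k gets id k-1.
    """
    return Graph.from_edges(_DEMO_EDGES)


def parent_chain_demo_graph() -> Graph:
    """Six vertices A..F on which repeated parent steps are easy to follow:
    from {A..F} the utmost vertex is F; after deleting it, C and E tie at
    the maximum distance from anchor A and the larger id E is deleted next.
    """
    return Graph.from_edges(
        [("A", "B"), ("B", "C"), ("A", "D"), ("D", "E"), ("E", "F")]
    )


def enumeration_demo_graph() -> Graph:
    """A 4-vertex diamond (complete graph minus the A-C edge) whose
    enumeration forest illustrates every child rejection case: D cannot join
    {A,B,C} (distance 1 < utmost distance 2), C cannot join {B,D} (equal
    distance but smaller id than the utmost D), and A cannot join {B}
    (below the anchor).  It has 14 connected vertex sets — every non-empty
    subset except the disconnected {A,C}."""
    return Graph.from_edges(
        [("A", "B"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
    )


def attributed_demo_graph() -> AttributedGraph:
    """A 6-vertex attributed graph on which, at s_min=2, all three prunings
    fire: roots C and H are covered at level one (by B and A), {A,F} is
    covered by its preceding sibling {A,B}, {A,B,C} and {A,B,G} are covered
    by {A,B,H}, and the child {A,B,F,H} repeats its parent's signature,
    cutting the remaining siblings.  Exactly two maximal cohesive subgraphs
    exist: {A,B,C,F,H} with dimensions {d0,d1} and {A,B,C,G,H} with
    dimensions {d0,d3}.
    """
    graph = Graph.from_edges(
        [("A", "B"), ("A", "F"), ("A", "H"), ("B", "C"), ("B", "G"), ("F", "H")]
    )
    dims = {
        "A": ("d0", "d1", "d2", "d3"),
        "B": ("d0", "d1", "d3", "d4"),
        "C": ("d0", "d1", "d3"),
        "F": ("d0", "d1", "d4"),
        "G": ("d0", "d2", "d3"),
        "H": ("d0", "d1", "d3"),
    }
    feature_sets = [dims[lab] for lab in graph.labels]
    return AttributedGraph.from_feature_sets(graph, feature_sets)
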