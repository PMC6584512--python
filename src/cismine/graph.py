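"""Immutable undirected graphs with a fixed vertex order, and plain-text I/O.

Vertices carry arbitrary string labels.  At load time the distinct labels are
sorted ascending and mapped to dense integer ids ``0..n-1``; every other module
compares vertices by these ids, so "lexicographically greater" always means
"numerically greater id".  Adjacency lists are strictly increasing tuples,
which makes neighbor iteration order (and therefore every downstream stream of
results) deterministic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

logger = logging.getLogger("cismine")

__all__ = [
    "CismineError",
    "EdgeListError",
    "AttributeTableError",
    "Graph",
    "AttributedGraph",
    "read_edge_list",
    "write_edge_list",
    "read_attributes",
    "write_vertex_sets",
]


class CismineError(Exception):
    """Base class for data errors raised by this package."""


class EdgeListError(CismineError):
    """Malformed or empty edge-list input."""


class AttributeTableError(CismineError):
    """Malformed or incomplete vertex-attribute table."""


@dataclass(frozen=True)
class Graph:
    """An undirected simple graph with a total order on vertices.

    Attributes
    ----------
    labels : tuple of str
        Original vertex labels, indexed by id; ascending (ids are assigned by
        sorting the distinct labels).
    adjacency : tuple of tuple of int
        ``adjacency[i]`` is the strictly increasing tuple of neighbors of
        vertex ``i``.  Symmetric, no self-loops, no duplicates.
    """

    labels: tuple[str, ...]
    adjacency: tuple[tuple[int, ...], ...]
    _label_to_id: dict[str, int] = field(repr=False, compare=False, hash=False, default_factory=dict)

    @property
    def n(self) -> int:
        """Number of vertices."""
        return len(self.labels)

    @property
    def m(self) -> int:
        """Number of edges."""
        return sum(len(a) for a in self.adjacency) // 2

    @property
    def max_degree(self) -> int:
        return max((len(a) for a in self.adjacency), default=0)

    def degree(self, v: int) -> int:
        return len(self.adjacency[v])

    def neighbors(self, v: int) -> tuple[int, ...]:
        return self.adjacency[v]

    def id_of(self, label: str) -> int:
        try:
            return self._label_to_id[label]
        except KeyError:
            raise KeyError(f"unknown vertex label {label!r}") from None

    def edges(self) -> Iterator[tuple[int, int]]:
        """Yield each edge once, as an (i, j) pair with i < j, ascending."""
        for i, adj in enumerate(self.adjacency):
            for j in adj:
                if j > i:
                    yield (i, j)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_vertices: Iterable[str] = (),
    ) -> "Graph":
        """Build a graph from labelled endpoint pairs.

        Self-loops and duplicate edges (in either orientation) are silently
        dropped here; :func:`read_edge_list` is the place that counts and
        warns about them.  ``extra_vertices`` adds labels that may have no
        incident edge (isolated vertices).
        """
        pairs: set[tuple[str, str]] = set()
        seen: set[str] = set(extra_vertices)
        for a, b in edges:
            seen.add(a)
            seen.add(b)
            if a == b:
                continue
            pairs.add((a, b) if a < b else (b, a))
        labels = tuple(sorted(seen))
        index = {lab: i for i, lab in enumerate(labels)}
        adj: list[set[int]] = [set() for _ in labels]
        for a, b in pairs:
            i, j = index[a], index[b]
            adj[i].add(j)
            adj[j].add(i)
        g = cls(labels=labels, adjacency=tuple(tuple(sorted(s)) for s in adj))
        g._label_to_id.update(index)
        return g

    def __post_init__(self) -> None:
        if not self._label_to_id:
            self._label_to_id.update({lab: i for i, lab in enumerate(self.labels)})


_VERTEX_DIRECTIVE = re.compile(r"^#\s*vertices?\s*:\s*(.*)$", re.IGNORECASE)


def read_edge_list(source: IO[str] | Iterable[str]) -> Graph:
    """Parse a whitespace-separated edge list into a :class:`Graph`.

    One edge per line, first two tokens are the endpoint labels, extra columns
    are ignored, ``#`` starts a comment line.  Every line is an undirected
    edge, so a reversed duplicate is a duplicate.  A comment directive of the
    form ``# vertices: a b c`` declares vertices explicitly; this is how
    isolated vertices enter the graph.  Self-loops and duplicate edges are
    dropped with a logged warning.

    Raises
    ------
    EdgeListError
        On a data line with fewer than two tokens (naming the line number) or
        when the input contains no edges and no declared vertices.
    """
    edges: list[tuple[str, str]] = []
    declared: list[str] = []
    seen_pairs: set[tuple[str, str]] = set()
    n_loops = 0
    n_dupes = 0
    for lineno, raw in enumerate(source, 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _VERTEX_DIRECTIVE.match(line)
            if m:
                declared.extend(m.group(1).split())
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise EdgeListError(
                f"line {lineno}: expected at least 2 whitespace-separated tokens, got {len(tokens)}"
            )
        a, b = tokens[0], tokens[1]
        if a == b:
            n_loops += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen_pairs:
            n_dupes += 1
            continue
        seen_pairs.add(key)
        edges.append((a, b))
    if not edges and not declared:
        raise EdgeListError("no edges or vertices")
    if n_loops:
        logger.warning("dropped %d self-loop(s)", n_loops)
    if n_dupes:
        logger.warning("dropped %d duplicate edge(s)", n_dupes)
    return Graph.from_edges(edges, extra_vertices=declared)


def write_edge_list(graph: Graph, sink: IO[str]) -> int:
    """Write the graph as a label edge list (one ``a<TAB>b`` line per edge).

    Isolated vertices are preserved through a ``# vertices:`` directive.
    Returns the number of edge lines written.  Output is deterministic, so
    write-then-read reproduces an identical structure and label→id mapping.
    """
    isolated = [graph.labels[i] for i in range(graph.n) if not graph.adjacency[i]]
    if isolated:
        sink.write("# vertices: " + " ".join(isolated) + "\n")
    count = 0
    for i, j in graph.edges():
        sink.write(f"{graph.labels[i]}\t{graph.labels[j]}\n")
        count += 1
    return count


@dataclass(frozen=True)
class AttributedGraph:
    """A graph whose vertices carry d-dimensional binary feature vectors.

    Each vector is stored as a Python int bitset: bit ``j`` (``1 << j``) is
    feature dimension ``j``.  ``feature_names[j]`` gives the dimension's name
    when the input supplied names; otherwise names default to the decimal
    dimension indices.
    """

    graph: Graph
    d: int
    features: tuple[int, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.d < 1:
            raise AttributeTableError("attribute dimension d must be >= 1")
        if len(self.features) != self.graph.n:
            raise AttributeTableError("one feature vector required per vertex")
        if len(self.feature_names) != self.d:
            raise AttributeTableError("one name required per feature dimension")

    def feature_vector(self, v: int) -> int:
        return self.features[v]

    def dims_of(self, bits: int) -> tuple[str, ...]:
        """Names of the set dimensions of a signature, in dimension order."""
        return tuple(self.feature_names[j] for j in range(self.d) if bits >> j & 1)

    @classmethod
    def from_feature_sets(
        cls, graph: Graph, feature_sets: Sequence[Iterable[str]]
    ) -> "AttributedGraph":
        """Build from per-vertex collections of feature names.

        d = number of distinct names; dimension order = ascending name sort.
        """
        names = sorted({f for fs in feature_sets for f in fs})
        if not names:
            raise AttributeTableError("no feature names present")
        dim = {name: j for j, name in enumerate(names)}
        bits = tuple(
            sum(1 << dim[f] for f in set(fs)) for fs in feature_sets
        )
        return cls(graph=graph, d=len(names), features=bits, feature_names=tuple(names))

    @classmethod
    def from_matrix(
        cls,
        graph: Graph,
        rows: Sequence[Sequence[int]],
        feature_names: Sequence[str] | None = None,
    ) -> "AttributedGraph":
        """Build from per-vertex 0/1 rows (row index = vertex id)."""
        if not rows or not rows[0]:
            raise AttributeTableError("empty attribute matrix")
        d = len(rows[0])
        bits = []
        for row in rows:
            if len(row) != d:
                raise AttributeTableError("inconsistent column counts in attribute matrix")
            bits.append(sum(1 << j for j, x in enumerate(row) if x))
        names = tuple(feature_names) if feature_names is not None else tuple(
            str(j) for j in range(d)
        )
        return cls(graph=graph, d=d, features=tuple(bits), feature_names=names)


def read_attributes(source: IO[str] | Iterable[str], graph: Graph) -> AttributedGraph:
    """Parse a vertex-attribute table aligned to ``graph``.

    Two whitespace/tab-separated dialects, auto-detected from the first data
    row:

    * binary matrix — ``label`` followed by d columns of 0/1;
    * feature list — ``label`` followed by one comma-separated list of
      feature names (a bare label means "no features").

    Every graph label must appear exactly once.  In the feature-list dialect
    d is the number of distinct names and dimension order is their ascending
    sort.

    Raises
    ------
    AttributeTableError
        On a vertex missing from (or duplicated in / unknown to) the table,
        a non-binary value in the matrix dialect, or inconsistent column
        counts.
    """
    rows: list[tuple[str, list[str]]] = []
    for lineno, raw in enumerate(source, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        rows.append((tokens[0], tokens[1:]))
    if not rows:
        raise AttributeTableError("empty attribute table")

    seen: dict[str, int] = {}
    for label, _ in rows:
        if label in seen:
            raise AttributeTableError(f"vertex {label!r} appears more than once in the attribute table")
        if label not in graph._label_to_id:
            raise AttributeTableError(f"vertex {label!r} in the attribute table is not in the graph")
        seen[label] = 1
    missing = [lab for lab in graph.labels if lab not in seen]
    if missing:
        raise AttributeTableError(f"vertex {missing[0]!r} missing from the attribute table")

    first_values = rows[0][1]
    matrix_dialect = bool(first_values) and all(t in ("0", "1") for t in first_values)

    if matrix_dialect:
        d = len(first_values)
        matrix: list[list[int]] = [[] for _ in range(graph.n)]
        for label, values in rows:
            if len(values) != d:
                raise AttributeTableError(
                    f"vertex {label!r}: expected {d} attribute columns, got {len(values)}"
                )
            parsed = []
            for t in values:
                if t not in ("0", "1"):
                    raise AttributeTableError(
                        f"vertex {label!r}: non-binary attribute value {t!r}"
                    )
                parsed.append(int(t))
            matrix[graph.id_of(label)] = parsed
        return AttributedGraph.from_matrix(graph, matrix)

    feature_sets: list[list[str]] = [[] for _ in range(graph.n)]
    for label, values in rows:
        if len(values) > 1:
            raise AttributeTableError(
                f"vertex {label!r}: feature-list rows take a single comma-separated column"
            )
        names = [f for f in values[0].split(",") if f] if values else []
        feature_sets[graph.id_of(label)] = names
    return AttributedGraph.from_feature_sets(graph, feature_sets)


def write_attributes(agraph: AttributedGraph, sink: IO[str]) -> int:
    """Write the binary-matrix attribute dialect; returns rows written."""
    g = agraph.graph
    for v in range(g.n):
        bits = agraph.features[v]
        cols = "\t".join(str(bits >> j & 1) for j in range(agraph.d))
        sink.write(f"{g.labels[v]}\t{cols}\n")
    return g.n


def write_vertex_sets(
    sets: Iterable[Iterable[int]], graph: Graph, sink: IO[str]
) -> int:
    """Write one vertex set per line: member labels in ascending id order,
    tab-separated.  Returns the number of lines written."""
    count = 0
    n = graph.n
    for s in sets:
        ids = sorted(s)
        if ids and (ids[0] < 0 or ids[-1] >= n):
            raise ValueError(f"vertex id out of range in {ids}")
        sink.write("\t".join(graph.labels[i] for i in ids) + "\n")
        count += 1
    return count
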