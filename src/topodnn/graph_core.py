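"""Undirected simple graphs, degrees, and degree-based edge partitions.

Every degree-based topological index is a sum (or product) over edges of a
symmetric function of the two endpoint degrees.  The *edge partition method*
of chemical graph theory groups edges into classes with identical endpoint
degree pairs, so the index collapses to a small weighted sum over classes.
This module provides the brute-force side of that picture: an explicit graph
container, exact degree computation, and the partition of the edge set by
canonical degree pairs.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Hashable, Iterable, Mapping
from dataclasses import dataclass

import networkx as nx

Node = Hashable


class GraphValidationError(ValueError):
    """Raised when input violates the simple-graph invariants."""


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph with opaque node identifiers.

    ``nodes`` preserves declaration order; ``edges`` preserves input order
    with each pair in its as-given orientation.  No self-loops, no duplicate
    edges (unordered), every endpoint declared.  Isolated nodes are allowed;
    they contribute to no edge class.  Instances are built through
    :func:`build_graph`, which enforces the invariants.
    """

    nodes: tuple[Node, ...]
    edges: tuple[tuple[Node, Node], ...]

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        """Export to a :class:`networkx.Graph` (nodes and edges, no data)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True, eq=True)
class EdgePartition:
    """Multiset of canonical degree pairs ``(a, b)``, ``a <= b``, with counts.

    Two identities tie a partition back to its source graph and are checked
    by :meth:`validate_against`: the counts sum to ``|E|``, and
    ``sum(count * (a + b))`` equals ``sum(d_v ** 2)`` (each vertex's degree
    is counted once per incident edge).
    """

    classes: Mapping[tuple[int, int], int]

    def __post_init__(self) -> None:
        for (a, b), count in self.classes.items():
            if not (isinstance(a, int) and isinstance(b, int) and 1 <= a <= b):
                raise GraphValidationError(
                    f"degree pair {(a, b)!r} is not canonical (need 1 <= a <= b)"
                )
            if not (isinstance(count, int) and count > 0):
                raise GraphValidationError(
                    f"class {(a, b)!r} has non-positive count {count!r}"
                )

    @property
    def total_edges(self) -> int:
        return sum(self.classes.values())

    def validate_against(self, graph: Graph) -> None:
        """Assert both partition identities against ``graph`` (exact)."""
        if self.total_edges != graph.num_edges:
            raise GraphValidationError(
                f"partition counts sum to {self.total_edges}, "
                f"graph has {graph.num_edges} edges"
            )
        degree_sq = sum(d * d for d in degree_map(graph).values())
        weighted = sum(count * (a + b) for (a, b), count in self.classes.items())
        if weighted != degree_sq:
            raise GraphValidationError(
                f"sum count*(a+b) = {weighted} != sum d_v^2 = {degree_sq}"
            )


def build_graph(
    nodes: Iterable[Node], edge_pairs: Iterable[tuple[Node, Node]]
) -> Graph:
    """Validate and assemble a simple undirected graph.

    Raises :class:`GraphValidationError` on a self-loop, a duplicate edge
    (in either orientation), or an endpoint that is not a declared node.
    Duplicates are an error rather than a silent merge so that malformed
    edge lists surface immediately.
    """
    node_tuple = tuple(nodes)
    declared = set(node_tuple)
    if len(node_tuple) == 0:
        raise GraphValidationError("graph must have at least one node")
    if len(declared) != len(node_tuple):
        raise GraphValidationError("duplicate node identifiers")

    edges: list[tuple[Node, Node]] = []
    seen: set[frozenset] = set()
    for u, v in edge_pairs:
        if u == v:
            raise GraphValidationError(f"self-loop on node {u!r}")
        if u not in declared or v not in declared:
            raise GraphValidationError(f"edge ({u!r}, {v!r}) has undeclared endpoint")
        key = frozenset((u, v))
        if key in seen:
            raise GraphValidationError(f"duplicate edge ({u!r}, {v!r})")
        seen.add(key)
        edges.append((u, v))
    return Graph(nodes=node_tuple, edges=tuple(edges))


def from_networkx(g: nx.Graph) -> Graph:
    """Import a networkx graph, validating the simple-graph invariants."""
    return build_graph(g.nodes(), g.edges())


def degree_map(graph: Graph) -> dict[Node, int]:
    """Degree of every node: the number of incident edges.

    Isolated nodes map to 0.  The handshake identity
    ``sum(degrees) == 2 * |E|`` holds by construction.
    """
    counts = Counter()
    for u, v in graph.edges:
        counts[u] += 1
        counts[v] += 1
    return {node: counts.get(node, 0) for node in graph.nodes}


def edge_partition(graph: Graph) -> EdgePartition:
    """Partition the edges by canonical endpoint-degree pair.

    Each edge ``uv`` lands in class ``(min(d_u, d_v), max(d_u, d_v))``;
    classes with coincident canonical pairs merge by summing counts.  The
    index functionals are symmetric in the two degrees, so merging changes
    no index value.
    """
    degrees = degree_map(graph)
    counts: Counter[tuple[int, int]] = Counter()
    for u, v in graph.edges:
        a, b = degrees[u], degrees[v]
        counts[(a, b) if a <= b else (b, a)] += 1
    ordered = dict(sorted(counts.items()))
    return EdgePartition(classes=ordered)
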