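"""Graph container, validation, and readers/writers for edge lists, GML, and partitions.

The in-memory graph is a :class:`networkx.Graph` whose nodes are opaque
identifiers (strings, when read from disk) and whose edges carry a positive
``weight`` attribute (implicitly 1 where absent).  All readers enforce the
contract every downstream computation relies on: undirected, no self-loops,
no duplicate edges, strictly positive weights.
"""

from __future__ import annotations

import os
from typing import Hashable, Iterable

import networkx as nx

__all__ = [
    "GraphFormatError",
    "canonical_sort",
    "read_edge_list",
    "write_edge_list",
    "read_gml",
    "neighbors",
    "strength",
    "validate_graph",
    "read_partition",
    "write_partition",
]


class GraphFormatError(ValueError):
    """Raised when an input file violates the graph or partition format."""


def canonical_sort(nodes: Iterable[Hashable]) -> list:
    """Sort node identifiers canonically.

    Numeric-aware when every identifier parses as an integer (so ``"10"``
    sorts after ``"9"``), lexicographic on the string form otherwise.  This
    single total order is used everywhere a deterministic node order is
    needed: tie-breaking, community-id canonicalization, file output.
    """
    items = list(nodes)
    try:
        return sorted(items, key=lambda x: int(x))
    except (TypeError, ValueError):
        return sorted(items, key=str)


def validate_graph(graph: nx.Graph) -> None:
    """Check the invariants all algorithms assume; raise ``GraphFormatError``.

    Undirected simple graph, no self-loops, every edge weight > 0.
    """
    if graph.is_directed():
        raise GraphFormatError("graph must be undirected")
    if graph.is_multigraph():
        raise GraphFormatError("multigraphs are not supported")
    for u, v, data in graph.edges(data=True):
        if u == v:
            raise GraphFormatError(f"self-loop on node {u!r}")
        w = data.get("weight", 1)
        if not w > 0:
            raise GraphFormatError(f"non-positive weight {w!r} on edge ({u!r}, {v!r})")


def read_edge_list(
    path: str | os.PathLike,
    delimiter: str | None = None,
    weighted: bool | None = None,
) -> nx.Graph:
    """Read a 2- or 3-column whitespace/TAB-delimited edge list.

    Parameters
    ----------
    path
        File with one edge per line: ``node_a node_b [weight]``.  Lines
        starting with ``#`` and blank lines are skipped.  Node identifiers
        are kept verbatim as strings.
    delimiter
        Field separator; ``None`` splits on any whitespace.
    weighted
        ``True`` requires a third column, ``False`` forbids it, ``None``
        (default) accepts either; missing weights default to 1.

    Raises
    ------
    GraphFormatError
        On malformed lines (with line number), non-positive weights,
        self-loops, or duplicate edges.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) not in (2, 3):
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}"
                )
            if weighted is True and len(fields) != 3:
                raise GraphFormatError(f"{path}:{lineno}: weight column required")
            if weighted is False and len(fields) != 2:
                raise GraphFormatError(f"{path}:{lineno}: unexpected weight column")
            u, v = fields[0], fields[1]
            if u == v:
                raise GraphFormatError(f"{path}:{lineno}: self-loop on node {u!r}")
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise GraphFormatError(
                        f"{path}:{lineno}: weight {fields[2]!r} is not a number"
                    ) from None
                if not w > 0:
                    raise GraphFormatError(
                        f"{path}:{lineno}: weight must be positive, got {w}"
                    )
            else:
                w = 1.0
            if graph.has_edge(u, v):
                raise GraphFormatError(f"{path}:{lineno}: duplicate edge ({u!r}, {v!r})")
            graph.add_edge(u, v, weight=w)
    return graph


def write_edge_list(graph: nx.Graph, path: str | os.PathLike) -> None:
    """Write a TAB-delimited edge list, canonical node and edge order.

    The weight column is emitted only when some edge weight differs from 1,
    so unweighted graphs round-trip to two columns.
    """
    order = {u: i for i, u in enumerate(canonical_sort(graph.nodes))}
    edges = sorted(
        ((u, v) if order[u] <= order[v] else (v, u) for u, v in graph.edges),
        key=lambda e: (order[e[0]], order[e[1]]),
    )
    any_weight = any(d.get("weight", 1) != 1 for _, _, d in graph.edges(data=True))
    with open(path, "w") as fh:
        for u, v in edges:
            if any_weight:
                w = graph.edges[u, v].get("weight", 1)
                fh.write(f"{u}\t{v}\t{w!r}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_gml(path: str | os.PathLike) -> nx.Graph:
    """Read a GML file into a validated undirected graph.

    Node names are taken from the GML ``label`` attribute when present,
    otherwise from ``id``; both are coerced to strings.  The edge ``value``
    attribute, when present, becomes the weight.  Directed GML is rejected.
    """
    raw = nx.read_gml(path, label="id")
    if raw.is_directed():
        raise GraphFormatError(f"{path}: directed graphs are not supported")
    graph = nx.Graph()
    names: dict[Hashable, str] = {}
    for node, data in raw.nodes(data=True):
        name = str(data.get("label", node))
        if name in names.values():
            raise GraphFormatError(f"{path}: duplicate node label {name!r}")
        names[node] = name
        graph.add_node(name)
    for u, v, data in raw.edges(data=True):
        a, b = names[u], names[v]
        if a == b:
            raise GraphFormatError(f"{path}: self-loop on node {a!r}")
        if graph.has_edge(a, b):
            raise GraphFormatError(f"{path}: duplicate edge ({a!r}, {b!r})")
        w = float(data.get("value", 1))
        if not w > 0:
            raise GraphFormatError(f"{path}: non-positive weight on edge ({a!r}, {b!r})")
        graph.add_edge(a, b, weight=w)
    return graph


def neighbors(graph: nx.Graph, x: Hashable) -> set:
    """The 1-degree neighborhood Γ₁(x): nodes sharing an edge with ``x``."""
    if x not in graph:
        raise KeyError(f"unknown node {x!r}")
    return set(graph[x])


def strength(graph: nx.Graph, x: Hashable) -> float:
    """Node strength s_x = Σ_{i∈Γ₁(x)} λ_ix (degree on unweighted graphs)."""
    if x not in graph:
        raise KeyError(f"unknown node {x!r}")
    return float(sum(d.get("weight", 1) for _, _, d in graph.edges(x, data=True)))


def write_partition(partition, path: str | os.PathLike, graph: nx.Graph | None = None) -> None:
    """Write a partition as a TAB-delimited ``node TAB community_id`` file.

    Rows are sorted by canonical node order and community ids are the
    canonical consecutive integers (first appearance in sorted node order),
    so two equal partitions always produce byte-identical files.  When
    ``graph`` is given, every graph node must be covered.
    """
    from .metrics import Partition

    if graph is not None:
        missing = set(graph.nodes) - set(partition.assignment)
        if missing:
            raise GraphFormatError(f"partition missing nodes: {canonical_sort(missing)!r}")
    canon = Partition(partition.assignment) if partition.assignment else partition
    with open(path, "w") as fh:
        for node in canonical_sort(canon.assignment):
            fh.write(f"{node}\t{canon.assignment[node]}\n")


def read_partition(path: str | os.PathLike):
    """Read a two-column ``node TAB community`` table into a Partition."""
    from .metrics import Partition

    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            node, comm = fields
            if node in assignment:
                raise GraphFormatError(f"{path}:{lineno}: node {node!r} listed twice")
            assignment[node] = comm
    return Partition(assignment)
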