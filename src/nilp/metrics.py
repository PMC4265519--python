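"""Partitions and partition-comparison metrics (normalized mutual information).

NMI here is the sum-normalized variant standard in community detection,
``2·I(X;Y) / (H(X)+H(Y))`` with natural logarithms, computed from the
contingency table of community co-memberships.  It is 1 for identical
partitions, 0 for independent ones.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Mapping

import numpy as np

from .graph_io import canonical_sort

__all__ = ["Partition", "confusion_table", "nmi"]


class Partition:
    """A hard partition of a node set into communities.

    Community ids are canonicalized on construction: consecutive integers
    from 0, assigned by first appearance when nodes are visited in canonical
    order.  Two partitions with the same blocks therefore compare equal
    regardless of the labels they were built from.
    """

    __slots__ = ("assignment", "_communities")

    def __init__(self, assignment: Mapping[Hashable, Hashable]):
        canon: dict[Hashable, int] = {}
        relabel: dict[Hashable, int] = {}
        for node in canonical_sort(assignment):
            raw = assignment[node]
            if raw not in relabel:
                relabel[raw] = len(relabel)
            canon[node] = relabel[raw]
        self.assignment: dict[Hashable, int] = canon
        self._communities: list[set] | None = None

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable[Hashable]]) -> "Partition":
        assignment: dict[Hashable, int] = {}
        for cid, block in enumerate(communities):
            for node in block:
                if node in assignment:
                    raise ValueError(f"node {node!r} appears in two communities")
                assignment[node] = cid
        return cls(assignment)

    @property
    def communities(self) -> list[set]:
        """Blocks as node sets, indexed by canonical community id."""
        if self._communities is None:
            blocks: list[set] = [set() for _ in range(self.n_communities)]
            for node, cid in self.assignment.items():
                blocks[cid].add(node)
            self._communities = blocks
        return self._communities

    @property
    def nodes(self) -> set:
        return set(self.assignment)

    @property
    def n_communities(self) -> int:
        return max(self.assignment.values(), default=-1) + 1

    def __len__(self) -> int:
        return len(self.assignment)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.assignment == other.assignment

    def __repr__(self) -> str:
        return f"Partition(n={len(self)}, communities={self.n_communities})"


def _aligned_labels(p1: Partition, p2: Partition) -> tuple[np.ndarray, np.ndarray]:
    if p1.nodes != p2.nodes:
        raise ValueError("partitions cover different node sets")
    if not p1.assignment:
        raise ValueError("partitions are empty")
    nodes = canonical_sort(p1.nodes)
    x = np.array([p1.assignment[u] for u in nodes], dtype=np.intp)
    y = np.array([p2.assignment[u] for u in nodes], dtype=np.intp)
    return x, y


def confusion_table(p1: Partition, p2: Partition) -> np.ndarray:
    """Contingency table: entry (i, j) = |community i of p1 ∩ community j of p2|.

    Row sums are p1's community sizes, column sums p2's, total n.
    """
    x, y = _aligned_labels(p1, p2)
    table = np.zeros((p1.n_communities, p2.n_communities), dtype=np.int64)
    np.add.at(table, (x, y), 1)
    return table


def nmi(p1: Partition, p2: Partition) -> float:
    """Normalized mutual information 2·I/(H1+H2) between two partitions.

    Natural logarithms; value in [0, 1].  When both entropies are zero the
    partitions are identical one-block partitions and the value is defined
    as 1; when exactly one entropy is zero the mutual information vanishes
    and the value is 0.
    """
    table = confusion_table(p1, p2).astype(float)
    n = table.sum()
    pij = table / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    h1 = -np.sum(pi * np.log(pi, where=pi > 0, out=np.zeros_like(pi)))
    h2 = -np.sum(pj * np.log(pj, where=pj > 0, out=np.zeros_like(pj)))
    if h1 == 0.0 and h2 == 0.0:
        return 1.0
    outer = np.outer(pi, pj)
    mask = pij > 0
    mi = float(np.sum(pij[mask] * np.log(pij[mask] / outer[mask])))
    value = 2.0 * mi / (h1 + h2)
    # clip float residue so the contract value ∈ [0, 1] holds exactly
    return min(1.0, max(0.0, value))
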