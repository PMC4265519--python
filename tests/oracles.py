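"""Independent reference implementations used only to cross-check the package.

These deliberately take different computational routes from the library:
exact rational recursion, dense matrix powers, and plain-Python direct
summation, versus the library's sparse float averaging and vectorized
contingency tables.
"""

from __future__ import annotations

import math
from collections import Counter
from fractions import Fraction

import networkx as nx
import numpy as np

from nilp import canonical_sort


def impact_exact(graph: nx.Graph, alpha: int) -> dict:
    """Exact-rational neighborhood impact for unweighted graphs."""
    values = {u: Fraction(1, graph.degree(u)) for u in graph}
    for _ in range(alpha - 1):
        values = {
            u: sum(values[v] for v in graph[u]) / Fraction(graph.degree(u))
            for u in graph
        }
    return values


def impact_dense(graph: nx.Graph, alpha: int) -> dict:
    """Neighborhood impact via a dense row-normalized matrix power."""
    nodes = canonical_sort(graph.nodes)
    w = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    s = w.sum(axis=1)
    iso = s == 0
    safe = np.where(iso, 1.0, s)
    t = w / safe[:, None]
    v = np.where(iso, 1.0, 1.0 / safe)
    v = np.linalg.matrix_power(t, alpha - 1) @ v
    v = np.where(iso, 1.0, v)
    return dict(zip(nodes, v.tolist()))


def nmi_direct(labels_x: list, labels_y: list) -> float:
    """Direct-summation NMI, 2I/(H1+H2), natural logs, plain Python."""
    n = len(labels_x)
    cx = Counter(labels_x)
    cy = Counter(labels_y)
    cxy = Counter(zip(labels_x, labels_y))
    hx = -sum(c / n * math.log(c / n) for c in cx.values())
    hy = -sum(c / n * math.log(c / n) for c in cy.values())
    if hx == 0.0 and hy == 0.0:
        return 1.0
    mi = sum(
        c / n * math.log(n * c / (cx[a] * cy[b])) for (a, b), c in cxy.items()
    )
    return 2.0 * mi / (hx + hy)
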