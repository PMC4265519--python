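"""Synthetic benchmarks: a planted-partition generator and a 10-node fixture.

The generator is a degree-homogeneous planted-partition (stochastic block)
model driven by the two quantities that matter for label-propagation
benchmarks: the target mean degree ``k_avg`` and the mixing coefficient μ,
the expected fraction of each node's edges that leave its community.
μ → 0 gives cleanly separated communities; as μ grows toward 1 the planted
structure dissolves and detection becomes impossible.  Unlike full
LFR-style benchmarks it has Poisson (not power-law) degrees and fixed
community sizes, which it trades for a closed-form parameterization.

The fixture is a small two-community graph — a loose 6-node cluster tied
by one bridge to a 4-clique — whose node-7 impact values are exact simple
fractions (1/4, 5/16, 271/960 for α = 1, 2, 3), handy as a worked example
and as ground truth in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .metrics import Partition

__all__ = ["PlantedConfig", "planted_partition", "sample_network_fixture"]


@dataclass(frozen=True)
class PlantedConfig:
    """Parameters of the planted-partition model.

    Attributes
    ----------
    n
        Total node count; must equal ``sum(communities)``.
    communities
        Planted community sizes, each at least 2.
    k_avg
        Target mean degree (expected, not exact, per node).
    mu
        Mixing coefficient in [0, 1): expected fraction of a node's edges
        ending outside its community.
    seed
        Generator seed; the edge set is a deterministic function of the
        full config.
    """

    n: int
    communities: tuple[int, ...]
    k_avg: float
    mu: float
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "communities", tuple(self.communities))
        if self.n != sum(self.communities):
            raise ValueError(
                f"community sizes sum to {sum(self.communities)}, expected n={self.n}"
            )
        if any(c < 2 for c in self.communities):
            raise ValueError("every community must have at least 2 nodes")
        if not 0 <= self.mu < 1:
            raise ValueError(f"mu must be in [0, 1), got {self.mu}")
        if not 0 < self.k_avg < self.n:
            raise ValueError(f"k_avg must be in (0, n), got {self.k_avg}")


def planted_partition(config: PlantedConfig) -> tuple[nx.Graph, Partition]:
    """Sample a graph with planted communities and return it with its truth.

    Within community c of size s_c, each pair is linked with probability
    p_in = (1−μ)·k_avg/(s_c−1); pairs straddling communities b, c are
    linked with probability μ·k_avg·(1/(n−s_b) + 1/(n−s_c))/2, so the
    expected intra- and inter-degree of every node are (1−μ)·k_avg and
    μ·k_avg (exactly so for equal community sizes).  Node identifiers are
    the strings "0".."n−1" in block order; all edges have weight 1.

    Raises
    ------
    ValueError
        If some community is too small to host the required intra-degree
        (p_in would exceed 1).
    """
    sizes = list(config.communities)
    n, k, mu = config.n, config.k_avg, config.mu
    p = np.zeros((len(sizes), len(sizes)))
    for i, si in enumerate(sizes):
        p_in = (1 - mu) * k / (si - 1)
        if p_in > 1:
            raise ValueError(
                f"infeasible density: community of size {si} cannot host "
                f"expected intra-degree {(1 - mu) * k:.2f}"
            )
        p[i, i] = p_in
        for j in range(i + 1, len(sizes)):
            sj = sizes[j]
            p_out = mu * k * (1 / (n - si) + 1 / (n - sj)) / 2
            p[i, j] = p[j, i] = min(p_out, 1.0)
    sbm = nx.stochastic_block_model(sizes, p, seed=config.seed)
    graph = nx.Graph()
    graph.add_nodes_from(str(u) for u in sbm.nodes)
    graph.add_edges_from((str(u), str(v), {"weight": 1.0}) for u, v in sbm.edges)
    truth = Partition(
        {str(u): data["block"] for u, data in sbm.nodes(data=True)}
    )
    return graph, truth


#: Edge set of the 10-node sample network: nodes 1–6 form the left cluster
#: (node 6 bridging), nodes 7–10 a 4-clique on the right.
_FIXTURE_EDGES = [
    ("1", "2"), ("1", "3"), ("1", "4"), ("1", "5"), ("1", "6"),
    ("2", "4"), ("2", "5"),
    ("3", "4"), ("3", "5"),
    ("4", "5"), ("4", "6"),
    ("5", "6"),
    ("6", "7"),
    ("7", "8"), ("7", "9"), ("7", "10"),
    ("8", "9"), ("8", "10"),
    ("9", "10"),
]


def sample_network_fixture() -> tuple[nx.Graph, Partition]:
    """The 10-node unweighted sample network and its reference split.

    Degrees are 5,3,3,5,5,4 on the left and 4,3,3,3 on the right, giving
    node 7 the exact impacts VI⁽¹⁾ = 1/4, VI⁽²⁾ = 5/16, VI⁽³⁾ = 271/960.
    The reference partition is {1..6} vs {7..10}.
    """
    graph = nx.Graph()
    graph.add_edges_from((u, v, {"weight": 1.0}) for u, v in _FIXTURE_EDGES)
    truth = Partition.from_communities(
        [{"1", "2", "3", "4", "5", "6"}, {"7", "8", "9", "10"}]
    )
    return graph, truth
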