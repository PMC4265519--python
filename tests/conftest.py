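import hypothesis
import networkx as nx
import pytest

from nilp import Partition, sample_network_fixture

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def sample_graph():
    graph, _ = sample_network_fixture()
    return graph


@pytest.fixture(scope="session")
def sample_truth():
    _, truth = sample_network_fixture()
    return truth


@pytest.fixture(scope="session")
def two_cliques():
    """Two 5-cliques joined by a single bridge edge, planted split known."""
    graph = nx.Graph()
    left = [f"a{i}" for i in range(5)]
    right = [f"b{i}" for i in range(5)]
    for block in (left, right):
        for i, u in enumerate(block):
            for v in block[i + 1:]:
                graph.add_edge(u, v, weight=1.0)
    graph.add_edge(left[0], right[0], weight=1.0)
    truth = Partition.from_communities([set(left), set(right)])
    return graph, truth
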