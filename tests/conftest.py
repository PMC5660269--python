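import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def triangle_with_pendant():
    """Triangle A-B-C plus a pendant edge C-D, unit weights."""
    G = nx.Graph()
    for u, v in [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D")]:
        G.add_edge(u, v, weight=1.0)
    return G


@pytest.fixture
def two_k5s():
    """Two disjoint 5-cliques."""
    G = nx.Graph()
    import itertools

    for block in (["A1", "A2", "A3", "A4", "A5"], ["B1", "B2", "B3", "B4", "B5"]):
        for u, v in itertools.combinations(block, 2):
            G.add_edge(u, v, weight=1.0)
    return G
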