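import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def triangle():
    return nx.Graph([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def path3():
    return nx.Graph([("A", "B"), ("B", "C")])


@pytest.fixture
def star9():
    """Star: center C plus 8 leaves L1..L8."""
    return nx.Graph([("C", f"L{i}") for i in range(1, 9)])


def random_graph(seed: int, n_max: int = 10, p: float = 0.4) -> nx.Graph:
    """Seeded G(n, p) over string node labels, n in [2, n_max]."""
    import random

    rng = random.Random(seed)
    n = rng.randint(2, n_max)
    g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
    return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
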