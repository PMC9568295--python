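import random

import networkx as nx
import pytest

from topodnn import DNNSpec, Graph, from_networkx


def make_random_graph(seed: int) -> Graph:
    """Seeded Erdos-Renyi-style graph with at least one edge."""
    rng = random.Random(seed)
    while True:
        n = rng.randint(2, 14)
        p = rng.uniform(0.15, 0.7)
        g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
        if g.number_of_edges() >= 1:
            return from_networkx(g)


def make_random_spec(seed: int, max_depth: int = 8, max_width: int = 12) -> DNNSpec:
    rng = random.Random(seed)
    depth = rng.randint(1, max_depth)
    return DNNSpec(
        rng.randint(1, max_width),
        tuple(rng.randint(1, max_width) for _ in range(depth)),
        rng.randint(1, max_width),
    )


@pytest.fixture
def figure_arch() -> DNNSpec:
    """The worked 7-layer example: 4 inputs, hidden widths 4,5,6,4,3, 3 outputs."""
    return DNNSpec(4, (4, 5, 6, 4, 3), 3)


@pytest.fixture
def path3() -> DNNSpec:
    """Smallest member DNN(1;[1];1): a 3-node path."""
    return DNNSpec(1, (1,), 1)
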