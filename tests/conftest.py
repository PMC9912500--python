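import itertools
import random

import pytest

from effectpath import build_dag, make_model


@pytest.fixture(scope="session")
def fig1b_model():
    return make_model("fig1b")


@pytest.fixture(scope="session")
def fig1b_dag(fig1b_model):
    return fig1b_model.dag


@pytest.fixture(scope="session")
def fig1b_roles(fig1b_model):
    return fig1b_model.roles


def random_dag(rng: random.Random, max_nodes: int = 7, edge_prob: float = 0.4):
    """A random DAG on at most ``max_nodes`` nodes via a random causal order."""
    k = rng.randint(2, max_nodes)
    labels = [f"N{i}" for i in range(k)]
    order = labels[:]
    rng.shuffle(order)
    edges = []
    for i in range(k):
        for j in range(i + 1, k):
            if rng.random() < edge_prob:
                edges.append((order[i], order[j]))
    return build_dag(edges, isolated=labels)


def all_conditioning_sets(dag, x, y):
    others = sorted(n for n in dag.nodes if n not in (x, y))
    for r in range(len(others) + 1):
        yield from itertools.combinations(others, r)
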