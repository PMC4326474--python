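import numpy as np
import pandas as pd
import pytest

import xgram


@pytest.fixture
def path_network():
    """Path graph 1-2-3-4."""
    return xgram.InteractionNetwork.from_edges([("1", "2"), ("2", "3"), ("3", "4")])


@pytest.fixture
def identity_ordering_2000():
    genes = [f"g{i:04d}" for i in range(2000)]
    return xgram.GeneOrdering(genes)


@pytest.fixture
def clustered_expression():
    """2000 genes in 10 clusters of 200, two conditions, default replication."""
    genes = [f"g{i:04d}" for i in range(2000)]
    labels = {g: i // 200 for i, g in enumerate(genes)}
    spec = xgram.SyntheticExpressionSpec(seed=3)
    signals = xgram.make_signal(labels, conditions=("A", "B"), seed=3)
    expression, design, truth = xgram.make_expression(labels, spec, signals)
    return expression, design, truth, labels


def random_network(rng, n_max=30, p=0.3):
    """Random simple graph with at least one edge, as an InteractionNetwork."""
    import networkx as nx

    while True:
        n = int(rng.integers(4, n_max + 1))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() > 0:
            return xgram.InteractionNetwork.from_edges(
                [(str(a), str(b)) for a, b in g.edges()]
            )


def random_ordering(rng, network):
    perm = rng.permutation(network.n_nodes)
    return xgram.GeneOrdering([network.nodes[j] for j in perm])


def dense_cost(network, ordering, alpha, beta):
    """Independent seriation-cost oracle: builds the permuted adjacency
    matrix explicitly and evaluates the definition term by term."""
    n = network.n_nodes
    pos = ordering.permutation_for(network)
    a = np.zeros((n, n))
    for iu, iv in network.edge_index:
        a[pos[iu], pos[iv]] = 1
        a[pos[iv], pos[iu]] = 1
    f = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if a[i, j]:
                f += abs(i - j) ** alpha
    d = np.abs(a[:-1, :] - a[1:, :]).sum() + np.abs(a[:, :-1] - a[:, 1:]).sum()
    return f + beta * d
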