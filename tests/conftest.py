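import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coregnet import CoexpressionNetwork, ExpressionDataset


@pytest.fixture
def tiny_dataset():
    """3 genes x 6 samples (one species, two conditions, triplicates)."""
    cols = [f"Ta_{c}_{r}" for c in ("cellulose", "glucose") for r in (1, 2, 3)]
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
         [0.0, 0.0, 0.0, 5.0, 6.0, 7.0],
         [0.0, 0.0, 0.0, 0.0, 1.0, 0.0]],
        index=["g1", "g2", "g3"],
        columns=cols,
    )
    return ExpressionDataset(values)


@pytest.fixture
def two_clique_path_net():
    """Two 4-cliques {a,b,c,d} and {g,h,i,j} joined by the path d-e-f-g."""
    g = nx.Graph()
    for clique in (["a", "b", "c", "d"], ["g", "h", "i", "j"]):
        g.add_edges_from(
            (u, v) for i, u in enumerate(clique) for v in clique[i + 1 :]
        )
    g.add_edges_from([("d", "e"), ("e", "f"), ("f", "g")])
    for u, v in g.edges:
        g.edges[u, v].update(r=1.0, hrr=1)
    return CoexpressionNetwork(g)


def as_network(g: nx.Graph) -> CoexpressionNetwork:
    for u, v in g.edges:
        g.edges[u, v].setdefault("r", 1.0)
        g.edges[u, v].setdefault("hrr", 1)
    return CoexpressionNetwork(g)


def brute_force_hrr_edges(genes, r, hrr_max):
    """Independent HRR oracle: explicit rank counting per ordered pair.

    rank(g, h) = 1 + number of third genes k that g prefers to h, where
    preference is higher r, ties broken by lexicographically smaller ID.
    Completely avoids sorting and the rank-matrix code path.
    """
    n = len(genes)

    def prefers(i, j, k):
        # does gene i prefer neighbour j over neighbour k?
        if r[i, j] != r[i, k]:
            return r[i, j] > r[i, k]
        return genes[j] < genes[k]

    def rank(i, j):
        return 1 + sum(
            1 for k in range(n) if k != i and k != j and prefers(i, k, j)
        )

    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if max(rank(i, j), rank(j, i)) <= hrr_max:
                edges.add((min(genes[i], genes[j]), max(genes[i], genes[j])))
    return edges


def random_correlation(rng, n, tie_fraction=0.0):
    """Symmetric matrix of fake correlations in [-1, 1], optional exact ties."""
    m = rng.uniform(-1, 1, size=(n, n))
    r = np.triu(m, 1)
    r = r + r.T
    np.fill_diagonal(r, 1.0)
    if tie_fraction > 0:
        # quantize to force exact ties between distinct pairs
        levels = max(2, int(1 / tie_fraction))
        r = np.round(r * levels) / levels
        np.fill_diagonal(r, 1.0)
    return r
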