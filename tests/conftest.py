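"""Shared fixtures and independent oracles for the test suite."""

from itertools import combinations

import networkx as nx
import pytest

from fullertk._spiralkernels import canonical_code_py, windup_adj_py
from fullertk.spiral import SpiralCode, enumerate_codes, windup_dual

# standard icosahedron adjacency, hand-coded: apex 0, upper ring 1-5,
# lower ring 6-10, apex 11
ICOSAHEDRON_EDGES = [
    (0, 1), (0, 2), (0, 3), (0, 4), (0, 5),
    (1, 2), (2, 3), (3, 4), (4, 5), (5, 1),
    (1, 6), (2, 6), (2, 7), (3, 7), (3, 8),
    (4, 8), (4, 9), (5, 9), (5, 10), (1, 10),
    (6, 7), (7, 8), (8, 9), (9, 10), (10, 6),
    (6, 11), (7, 11), (8, 11), (9, 11), (10, 11),
]


@pytest.fixture(scope="session")
def icosahedron_graph():
    return nx.Graph(ICOSAHEDRON_EDGES)


@pytest.fixture(scope="session")
def c20_dual():
    return windup_dual(enumerate_codes(20)[0])


@pytest.fixture(scope="session")
def c24_dual():
    return windup_dual(enumerate_codes(24)[0])


def adj_to_graph(adj) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(adj)))
    for u, nbrs in enumerate(adj):
        g.add_edges_from((u, v) for v in nbrs if u < v)
    return g


def brute_force_canonical_codes(n: int) -> list[SpiralCode]:
    """Oracle: scan all 12-subsets of face positions, wind up, keep the
    self-canonical ones.  Only viable for small n."""
    m = n // 2 + 2
    out = []
    for sub in combinations(range(m), 12):
        caps = [6] * m
        for p in sub:
            caps[p] = 5
        adj = windup_adj_py(caps)
        if adj is None:
            continue
        if canonical_code_py([set(s) for s in adj], caps) == tuple(caps):
            out.append(SpiralCode(n, tuple(p + 1 for p in sub)))
    return sorted(out)


def relabel_dual_adj(adj, seed: int):
    """Random relabelling of adjacency sets (for invariance tests)."""
    import random

    rng = random.Random(seed)
    m = len(adj)
    perm = list(range(m))
    rng.shuffle(perm)
    new = [set() for _ in range(m)]
    for u, nbrs in enumerate(adj):
        for v in nbrs:
            new[perm[u]].add(perm[v])
    return new
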