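import math
from itertools import combinations

import networkx as nx
import pytest

from tfcoop.resources import PPINetwork, TFPair
from tfcoop.synthetic import WorldParams, generate_world


@pytest.fixture
def path_network():
    """a - x - y - b plus an isolated edge (u, v)."""
    return PPINetwork([("a", "x"), ("x", "y"), ("y", "b"), ("u", "v")])


@pytest.fixture(scope="session")
def small_world():
    """A reduced synthetic world shared by fast tests."""
    params = WorldParams(
        n_genes=300, n_tfs=20, n_planted_pairs=10, n_background_pairs=40,
        n_null_score_pairs=5000, seed=11,
    )
    return generate_world(params)


# ---------------------------------------------------------------------------
# independent oracles (enumeration / brute force), kept free of tfcoop logic
# ---------------------------------------------------------------------------

def brute_force_overlap_tail(c: int, n_universe: int, n1: int, n2: int) -> float:
    """P(|S1 ∩ S2| >= c) by enumerating every placement of the second set.

    S1 is fixed to the first n1 universe elements; all C(n_universe, n2)
    placements of S2 are enumerated and counted.
    """
    universe = range(n_universe)
    s1 = set(range(n1))
    hits = total = 0
    for s2 in combinations(universe, n2):
        total += 1
        if len(s1 & set(s2)) >= c:
            hits += 1
    return hits / total


def brute_force_fisher_tail(n_universe: int, benchmark: set, n_predicted: int,
                            k_observed: int) -> float:
    """P(overlap >= k) over all equally likely predicted-set placements."""
    hits = total = 0
    for placement in combinations(range(n_universe), n_predicted):
        total += 1
        if len(benchmark & set(placement)) >= k_observed:
            hits += 1
    return hits / total


def brute_force_shortest_path(graph: nx.Graph, a, b):
    """Minimum simple-path edge count by depth-first enumeration, or None."""
    if a not in graph or b not in graph:
        return None
    best = None
    stack = [(a, {a}, 0)]
    while stack:
        node, visited, length = stack.pop()
        if node == b:
            if best is None or length < best:
                best = length
            continue
        if best is not None and length >= best:
            continue
        for nb in graph.neighbors(node):
            if nb not in visited:
                stack.append((nb, visited | {nb}, length + 1))
    return best


def brute_force_pearson(a, b):
    """Pearson r from the raw covariance formula."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)


def hub_pair_universe(n: int) -> list[TFPair]:
    """n distinct unordered TF pairs sharing a hub TF, for Fisher-test fixtures."""
    return [TFPair("HUB", f"T{i:02d}") for i in range(n)]


def hub_tf_universe(pool: list[TFPair]) -> frozenset[str]:
    return frozenset(t for p in pool for t in p)
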