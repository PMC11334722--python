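"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive subset enumeration,
isomorphism checks against networkx generator graphs, closed-form
combinatorics — and shares no code with the package internals it checks.
"""

from itertools import combinations
from math import comb

import networkx as nx

# reference patterns built from networkx generators, not from the package
PATTERNS = {
    "G0": nx.path_graph(2),
    "G1": nx.path_graph(3),
    "G2": nx.complete_graph(3),
    "G3": nx.path_graph(4),
    "G4": nx.star_graph(3),
    "G5": nx.cycle_graph(4),
    "G6": None,  # triangle with pendant, built below
    "G7": None,  # diamond
    "G8": nx.complete_graph(4),
}
_g6 = nx.complete_graph(3)
_g6.add_edge(0, 3)
PATTERNS["G6"] = _g6
_g7 = nx.complete_graph(4)
_g7.remove_edge(2, 3)
PATTERNS["G7"] = _g7


def classify_subgraph(sg: nx.Graph) -> str | None:
    """Graphlet id of a connected induced subgraph via isomorphism tests."""
    for gid, pattern in PATTERNS.items():
        if sg.number_of_nodes() == pattern.number_of_nodes() and \
                nx.is_isomorphic(sg, pattern):
            return gid
    return None


def brute_force_constrained_counts(graph: nx.Graph, seed_nodes: set) -> dict:
    """Constrained graphlet counts by exhaustive subset enumeration.

    A subset counts for its graphlet type when the induced subgraph is
    connected and admits an assignment with every node a seed except
    possibly one maximum-degree node (the intermediate, which may itself
    be a seed); 2-node subsets require both endpoints to be seeds.
    """
    counts = {f"G{i}": 0 for i in range(9)}
    nodes = sorted(graph.nodes)
    for size in (2, 3, 4):
        for sub in combinations(nodes, size):
            sg = graph.subgraph(sub)
            if not nx.is_connected(sg):
                continue
            non_seeds = [n for n in sub if n not in seed_nodes]
            if size == 2:
                if not non_seeds:
                    counts["G0"] += 1
                continue
            if len(non_seeds) > 1:
                continue
            degs = dict(sg.degree())
            max_deg = max(degs.values())
            if non_seeds and degs[non_seeds[0]] != max_deg:
                continue
            counts[classify_subgraph(sg)] += 1
    return counts


def brute_force_hypergeom_tail(k: int, M: int, K: int, n: int) -> float:
    """P[X >= k] by direct summation of the hypergeometric pmf."""
    total = comb(M, n)
    upper = min(n, K)
    return sum(comb(K, i) * comb(M - K, n - i) for i in range(k, upper + 1)) \
        / total


def random_graph_with_seeds(rng, max_nodes=12):
    """A random graph plus a random seed subset, for oracle comparisons."""
    n = int(rng.integers(4, max_nodes + 1))
    p = float(rng.uniform(0.15, 0.6))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    n_seeds = int(rng.integers(2, max(3, n // 2 + 1)))
    seeds = set(rng.choice(sorted(g.nodes), size=min(n_seeds, n),
                           replace=False))
    return g, seeds
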