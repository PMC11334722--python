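import numpy as np
import pytest

from graphflux import Interactome, SeedSet
from graphflux.synthetic import generate_interactome, plant_pathway


@pytest.fixture
def triangle():
    """Triangle a-b-c with seeds {a, b}."""
    inter = Interactome.from_edges(
        [("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.7)])
    return inter, SeedSet.from_nodes(["a", "b"], inter)


@pytest.fixture
def two_cliques():
    """Two 4-cliques joined by a single bridge edge."""
    edges = []
    for grp in ("abcd", "efgh"):
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((grp[i], grp[j], 1.0))
    edges.append(("d", "e", 1.0))
    return Interactome.from_edges(edges)


@pytest.fixture
def small_instance():
    """One deterministic planted-pathway benchmark instance."""
    inter = generate_interactome(200, 2, rng_seed=42)
    return plant_pathway(inter, 15, 0.5, rng_seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
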