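"""Graphlet catalogue, constrained counting, permutation null, GGN."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

import graphflux as gf
from graphflux.graphlets import (GRAPHLET_IDS, build_ggn,
                                 count_all_constrained, graphlet_catalogue)
from brute import (brute_force_constrained_counts, classify_subgraph,
                   random_graph_with_seeds)


class TestCatalogue:
    def test_nine_patterns_with_correct_orders(self):
        cat = graphlet_catalogue()
        assert len(cat) == 9
        orders = [g.order for g in cat]
        assert orders.count(2) == 1 and orders.count(3) == 2 \
            and orders.count(4) == 6

    def test_patterns_are_the_connected_graphs_on_2_to_4_nodes(self):
        # exhaustive: every catalogue pattern is connected, and no two are
        # isomorphic, which pins down the full set of 9
        pats = []
        for g in graphlet_catalogue():
            gg = nx.Graph()
            gg.add_nodes_from(range(g.order))
            gg.add_edges_from(tuple(e) for e in g.edge_pattern)
            assert nx.is_connected(gg)
            pats.append(gg)
        for a, b in combinations(pats, 2):
            assert not (a.number_of_nodes() == b.number_of_nodes()
                        and nx.is_isomorphic(a, b))

    def test_catalogue_matches_standard_numbering(self):
        # the id assignment agrees with the independent generator-built
        # patterns (G3 = path, G4 = star, G5 = cycle, G6 = tri+pendant...)
        for g in graphlet_catalogue():
            gg = nx.Graph()
            gg.add_nodes_from(range(g.order))
            gg.add_edges_from(tuple(e) for e in g.edge_pattern)
            assert classify_subgraph(gg) == g.id

    def test_intermediate_orbit_has_maximum_degree(self):
        for g in graphlet_catalogue():
            deg = {i: 0 for i in range(g.order)}
            for e in g.edge_pattern:
                for n in e:
                    deg[n] += 1
            max_deg = max(deg.values())
            assert all(deg[i] == max_deg for i in g.intermediate_orbit)

    def test_g8_is_the_4_clique(self):
        g8 = graphlet_catalogue()[-1]
        assert g8.id == "G8" and g8.n_edges == 6


class TestConstrainedCounting:
    def test_triangle_counts(self, triangle):
        inter, seeds = triangle
        assert gf.count_constrained(inter, seeds, "G2")[0] == 1
        assert gf.count_constrained(inter, seeds, "G0")[0] == 1
        assert gf.count_constrained(inter, seeds, "G1")[0] == 0

    def test_path_counts(self):
        inter = gf.Interactome.from_edges([("a", "b", 1.0), ("b", "c", 1.0)])
        seeds = gf.SeedSet.from_nodes(["a", "c"], inter)
        count, matches = gf.count_constrained(inter, seeds, "G1")
        assert count == 1
        assert matches[0].intermediate == "b"
        assert gf.count_constrained(inter, seeds, "G0")[0] == 0

    def test_star_counts(self):
        inter = gf.Interactome.from_edges(
            [("m", "s1", 1.0), ("m", "s2", 1.0), ("m", "s3", 1.0)])
        seeds = gf.SeedSet.from_nodes(["s1", "s2", "s3"], inter)
        assert gf.count_constrained(inter, seeds, "G4")[0] == 1
        assert gf.count_constrained(inter, seeds, "G1")[0] == 3

    def test_oracle_equivalence_on_random_graphs(self, rng):
        # the seed-anchored enumeration must agree with exhaustive
        # subset enumeration on every graphlet type
        for _ in range(40):
            g, seed_nodes = random_graph_with_seeds(rng)
            if g.number_of_edges() == 0:
                continue
            inter = gf.Interactome(
                nx.Graph((u, v, {"confidence": 1.0}) for u, v in g.edges))
            for n in g.nodes:
                inter.graph.add_node(n)
            seeds = gf.SeedSet.from_nodes(sorted(seed_nodes), inter)
            counts, _ = count_all_constrained(inter, seeds)
            expected = brute_force_constrained_counts(g, seed_nodes)
            assert counts == expected

    def test_adding_a_seed_never_decreases_counts(self, rng):
        for _ in range(10):
            g, seed_nodes = random_graph_with_seeds(rng, max_nodes=10)
            if g.number_of_edges() == 0:
                continue
            extra = sorted(set(g.nodes) - seed_nodes)
            if not extra:
                continue
            inter = gf.Interactome(
                nx.Graph((u, v, {"confidence": 1.0}) for u, v in g.edges))
            seeds = gf.SeedSet.from_nodes(sorted(seed_nodes), inter)
            more = gf.SeedSet.from_nodes(sorted(seed_nodes) + [extra[0]],
                                         inter)
            before, _ = count_all_constrained(inter, seeds)
            after, _ = count_all_constrained(inter, more)
            assert all(after[g_] >= before[g_] for g_ in GRAPHLET_IDS)

    def test_matches_are_induced_and_seed_covering(self, small_instance):
        inst = small_instance
        _, matches = count_all_constrained(inst.interactome, inst.seeds)
        seeds = inst.seeds.nodes
        for gid, mlist in matches.items():
            for m in mlist[:20]:
                non_seeds = m.nodes - seeds
                assert len(non_seeds) <= 1
                if gid != "G0":
                    assert len(m.nodes & seeds) >= 2


class TestPermutation:
    def test_degree_sequence_preserved(self, rng):
        for _ in range(5):
            g, _ = random_graph_with_seeds(rng)
            if g.number_of_edges() < 2:
                continue
            inter = gf.Interactome(
                nx.Graph((u, v, {"confidence": 0.5}) for u, v in g.edges))
            perm = gf.permute_network(inter, swap_factor=10,
                                      rng_seed=int(rng.integers(2**31)))
            assert sorted(d for _, d in perm.graph.degree()) \
                == sorted(d for _, d in inter.graph.degree())
            assert perm.n_edges == inter.n_edges

    def test_triangle_cannot_swap(self, triangle):
        inter, _ = triangle
        perm = gf.permute_network(inter, swap_factor=10, rng_seed=0)
        assert perm.edges == inter.edges

    def test_confidence_multiset_preserved(self, small_instance):
        inter = small_instance.interactome
        perm = gf.permute_network(inter, swap_factor=5, rng_seed=7)
        before = sorted(inter.confidence(*sorted(e)) for e in inter.edges)
        after = sorted(perm.confidence(*sorted(e)) for e in perm.edges)
        assert np.allclose(before, after)

    def test_deterministic_given_seed(self, small_instance):
        inter = small_instance.interactome
        a = gf.permute_network(inter, rng_seed=3)
        b = gf.permute_network(inter, rng_seed=3)
        assert a == b
        c = gf.permute_network(inter, rng_seed=4)
        assert a != c  # with 10|E| attempts a different shuffle is certain


class TestSignificance:
    def test_z_uses_sample_sd_of_permutation_counts(self, triangle):
        # star around a hub: G1 is observed; the z reported must equal
        # (obs - mean)/sd computed from the returned permutation counts
        inter = gf.Interactome.from_edges(
            [("m", "s1", 1.0), ("m", "s2", 1.0), ("m", "s3", 1.0),
             ("s1", "x", 1.0), ("x", "y", 1.0), ("y", "s2", 1.0)])
        seeds = gf.SeedSet.from_nodes(["s1", "s2", "s3"], inter)
        census = gf.graphlet_significance(inter, seeds, n_permutations=25,
                                          rng_seed=9)
        for gid in ("G1", "G4"):
            perm = census.perm_counts[gid]
            sd = np.std(perm, ddof=1)
            if sd > 0:
                expected = (census.observed[gid] - np.mean(perm)) / sd
                assert census.z[gid] == pytest.approx(expected)
                assert census.significant[gid] == (census.z[gid] > 1.65)

    def test_census_on_planted_instance_is_deterministic(self, small_instance):
        inst = small_instance
        a = gf.graphlet_significance(inst.interactome, inst.seeds,
                                     n_permutations=20, rng_seed=5)
        b = gf.graphlet_significance(inst.interactome, inst.seeds,
                                     n_permutations=20, rng_seed=5)
        assert a.observed == b.observed
        assert a.perm_counts == b.perm_counts
        assert a.z == b.z and a.significant == b.significant

    def test_zero_sd_tie_rule(self):
        # a graph with no legal swap gives identical permuted counts;
        # observed equals the null -> not significant
        inter = gf.Interactome.from_edges(
            [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        seeds = gf.SeedSet.from_nodes(["a", "b"], inter)
        census = gf.graphlet_significance(inter, seeds, n_permutations=10,
                                          rng_seed=0)
        assert not census.significant["G2"]
        assert not census.significant["G0"]

    def test_seed_dense_region_is_significant(self, small_instance):
        inst = small_instance
        census = gf.graphlet_significance(inst.interactome, inst.seeds,
                                          n_permutations=50, rng_seed=1)
        assert any(census.significant.values())


class TestGGN:
    def test_union_rule_single_triangle(self, triangle):
        inter, seeds = triangle
        counts, matches = count_all_constrained(inter, seeds)
        from graphflux.graphlets import GraphletCensus
        census = GraphletCensus(
            observed=counts, perm_counts={g: [0] for g in GRAPHLET_IDS},
            z={g: 0.0 for g in GRAPHLET_IDS},
            significant={g: g == "G2" for g in GRAPHLET_IDS})
        ggn = build_ggn(inter, seeds, census, matches)
        assert ggn.nodes == {"a", "b", "c"}
        assert ggn.n_edges == 3

    def test_no_significant_graphlet_gives_empty_ggn(self, triangle):
        inter, seeds = triangle
        counts, matches = count_all_constrained(inter, seeds)
        from graphflux.graphlets import GraphletCensus
        census = GraphletCensus(
            observed=counts, perm_counts={g: [0] for g in GRAPHLET_IDS},
            z={g: 0.0 for g in GRAPHLET_IDS},
            significant={g: False for g in GRAPHLET_IDS})
        ggn = build_ggn(inter, seeds, census, matches)
        assert ggn.n_nodes == 0 and ggn.n_edges == 0

    def test_ggn_contained_in_reference(self, small_instance):
        inst = small_instance
        census = gf.graphlet_significance(inst.interactome, inst.seeds,
                                          n_permutations=30, rng_seed=2)
        _, matches = count_all_constrained(inst.interactome, inst.seeds)
        ggn = build_ggn(inst.interactome, inst.seeds, census, matches)
        assert ggn.nodes <= inst.interactome.nodes
        assert ggn.edges <= inst.interactome.edges
        for e in ggn.edges:
            u, v = sorted(e)
            assert ggn.subgraph.confidence(u, v) \
                == inst.interactome.confidence(u, v)
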