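import numpy as np
import pytest

from patientnets.communities import (
    BipartiteGraph,
    FilterParams,
    InteractionKey,
    aggregate_networks,
    bipartite_modularity,
    build_bipartite,
    extract_community_subgraphs,
    filter_interaction_nodes,
    louvain_bipartite,
    select_lower_threshold,
    select_resolution,
    standard_modularity,
)
from patientnets.network import PatientNetwork

from ._oracles import brute_force_qb, exhaustive_best_qb
from .conftest import block_bipartite, random_bipartite


def net(patient, states, edges):
    return PatientNetwork(patient=patient, states=states, edges=edges, sources=set(states))


class TestAggregation:
    def test_inhibited_source_excluded(self):
        coll = {"p1": net("p1", {"Y": -1, "Z": 1}, [("Y", "Z", 1)])}
        with pytest.warns(UserWarning, match="no active interactions"):
            inc = aggregate_networks(coll)
        assert inc == {}

    def test_shared_interaction_counts_patients(self):
        e = [("X", "Y", 1)]
        coll = {
            "p1": net("p1", {"X": 1, "Y": 1}, e),
            "p2": net("p2", {"X": 1, "Y": -1}, e),
        }
        inc = aggregate_networks(coll)
        key = InteractionKey("X", 1, "Y")
        assert set(inc[key]) == {"p1", "p2"}
        assert inc[key]["p1"] == 1 and inc[key]["p2"] == -1

    def test_empty_collection_errors(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_networks({})


class TestBipartite:
    def test_shared_plus_private_construction(self):
        shared = InteractionKey("a", 1, "b")
        i1 = InteractionKey("c", 1, "d")
        i2 = InteractionKey("e", 1, "f")
        inc = {shared: {"p1": 1, "p2": 1}, i1: {"p1": 1}, i2: {"p2": 1}}
        b = build_bipartite(inc)
        assert (len(b.patients), len(b.interactions), b.m) == (2, 3, 4)
        assert b.interaction_degrees()[shared] == 2

    def test_single_patient_star(self):
        inc = {InteractionKey(f"s{k}", 1, f"t{k}"): {"p": 1} for k in range(5)}
        b = build_bipartite(inc)
        assert b.m == 5 and b.patient_degrees()["p"] == 5

    def test_degree_sum_identity(self):
        rng = np.random.default_rng(0)
        b = random_bipartite(rng, 5, 9)
        assert sum(b.patient_degrees().values()) == b.m
        assert sum(b.interaction_degrees().values()) == b.m


class TestFilter:
    def make(self, degrees):
        pats = [f"p{k}" for k in range(max(degrees.values()))]
        ints = list(degrees)
        adj = {p: set() for p in pats}
        for i, d in degrees.items():
            for p in pats[:d]:
                adj[p].add(i)
        return BipartiteGraph(pats, ints, adj)

    def test_exclusive_bounds(self):
        i1, i2, i3 = (InteractionKey(f"s{k}", 1, f"t{k}") for k in range(3))
        b = self.make({i1: 1, i2: 5, i3: 30})
        out = filter_interaction_nodes(b, FilterParams(4, 30, "exclusive"))
        assert out.interactions == [i2]
        assert len(out.patients) == len(b.patients)  # patients never removed

    def test_inclusive_bounds(self):
        i1, i2, i3 = (InteractionKey(f"s{k}", 1, f"t{k}") for k in range(3))
        b = self.make({i1: 1, i2: 5, i3: 30})
        out = filter_interaction_nodes(b, FilterParams(4, 30, "inclusive"))
        assert set(out.interactions) == {i2, i3}

    def test_singleton_exclusion_at_t_lower_one(self):
        i1, i2 = (InteractionKey(f"s{k}", 1, f"t{k}") for k in range(2))
        b = self.make({i1: 1, i2: 3})
        out = filter_interaction_nodes(b, FilterParams(1, 10, "exclusive"))
        assert out.interactions == [i2]

    def test_all_removed_errors(self):
        i1 = InteractionKey("s", 1, "t")
        b = self.make({i1: 1})
        with pytest.raises(ValueError, match="loosen"):
            filter_interaction_nodes(b, FilterParams(4, 30))

    def test_invalid_params(self):
        with pytest.raises(ValueError, match="t_lower"):
            FilterParams(5, 5)


class TestModularity:
    def test_all_in_one_community_is_zero(self):
        b = block_bipartite(2)
        labels = {n: 0 for n in b.patients + b.interactions}
        assert bipartite_modularity(b, labels) == pytest.approx(0.0, abs=1e-12)

    def test_two_k22_blocks_half(self):
        b = block_bipartite(2)
        labels = {n: (0 if "b0" in str(n) else 1) for n in b.patients + b.interactions}
        assert bipartite_modularity(b, labels) == pytest.approx(0.5)

    def test_singletons_zero(self):
        b = block_bipartite(2)
        labels = {n: k for k, n in enumerate(b.patients + b.interactions)}
        assert bipartite_modularity(b, labels) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            b = random_bipartite(rng)
            labels = {n: int(rng.integers(0, 3)) for n in b.patients + b.interactions}
            gamma = float(rng.uniform(0.5, 1.5))
            assert bipartite_modularity(b, labels, gamma) == pytest.approx(
                brute_force_qb(b, labels, gamma), abs=1e-12
            )

    def test_standard_modularity_all_in_one_zero(self):
        b = block_bipartite(2)
        labels = {n: 0 for n in b.patients + b.interactions}
        assert standard_modularity(b, labels) == pytest.approx(0.0, abs=1e-12)

    def test_standard_modularity_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(9)
        b = random_bipartite(rng, 5, 8)
        labels = {n: int(rng.integers(0, 3)) for n in b.patients + b.interactions}
        g = nx.Graph()
        g.add_nodes_from(b.patients + b.interactions)
        for p in b.patients:
            for i in b.adj[p]:
                g.add_edge(p, i)
        comms = {}
        for n, c in labels.items():
            comms.setdefault(c, set()).add(n)
        ref = nx.algorithms.community.modularity(g, comms.values())
        assert standard_modularity(b, labels) == pytest.approx(ref, abs=1e-12)

    def test_empty_graph_errors(self):
        b = BipartiteGraph(["p"], [InteractionKey("s", 1, "t")], {"p": set()})
        with pytest.raises(ValueError, match="m = 0"):
            bipartite_modularity(b, {"p": 0, InteractionKey("s", 1, "t"): 0})


class TestLouvain:
    def test_recovers_k33_blocks(self):
        b = block_bipartite(3)
        part = louvain_bipartite(b, gamma=1.0, seed=0)
        assert part.Q_b == pytest.approx(0.5)
        blocks = {part.labels[p] for p in b.patients if "b0" in p}
        assert len(blocks) == 1

    def test_single_edge_single_community(self):
        i = InteractionKey("s", 1, "t")
        b = BipartiteGraph(["p"], [i], {"p": {i}})
        part = louvain_bipartite(b, seed=0)
        assert part.labels["p"] == part.labels[i]

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        b = random_bipartite(rng, 6, 10)
        a = louvain_bipartite(b, seed=5)
        c = louvain_bipartite(b, seed=5)
        assert a.labels == c.labels and a.Q_b == c.Q_b

    def test_history_non_decreasing(self):
        rng = np.random.default_rng(3)
        b = random_bipartite(rng, 6, 12)
        part = louvain_bipartite(b, seed=1)
        assert all(b2 >= a2 - 1e-12 for a2, b2 in zip(part.history, part.history[1:]))

    def test_matches_exhaustive_optimum_on_small_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(6):
            b = random_bipartite(rng, int(rng.integers(2, 5)), int(rng.integers(2, 5)))
            part = louvain_bipartite(b, gamma=1.0, seed=0)
            assert part.Q_b == pytest.approx(exhaustive_best_qb(b), abs=1e-10)

    def test_gamma_validation(self):
        b = block_bipartite(2)
        with pytest.raises(ValueError, match="gamma"):
            louvain_bipartite(b, gamma=0.0)

    def test_larger_gamma_never_grows_largest_community(self):
        b = block_bipartite(3, n_blocks=3)
        sizes = []
        for gamma in (0.6, 1.0, 1.4):
            part = louvain_bipartite(b, gamma=gamma, seed=0)
            counts = {}
            for c in part.labels.values():
                counts[c] = counts.get(c, 0) + 1
            sizes.append(max(counts.values()))
        assert sizes == sorted(sizes, reverse=True) or len(set(sizes)) == 1


class TestSelection:
    def test_smallest_threshold_above_qmin(self):
        # three K33 blocks plus ubiquitous noise interactions shared by all
        b = block_bipartite(3, n_blocks=3)
        noise = [InteractionKey(f"noise{k}", 1, f"n{k}") for k in range(3)]
        for i in noise:
            b.interactions.append(i)
            for p in b.patients:
                b.adj[p].add(i)
        t, scores = select_lower_threshold(b, [1, 2, 3], gamma=1.0, seed=0, t_upper=8)
        assert t in (1, 2, 3)
        assert scores[t] > 0.3

    def test_fallback_to_argmax_with_warning(self):
        b = block_bipartite(2)
        with pytest.warns(UserWarning, match="argmax"):
            t, scores = select_lower_threshold(b, [1], gamma=1.0, seed=0, t_upper=10, q_min=0.99)
        assert t == 1

    def test_empty_candidates_error(self):
        b = block_bipartite(2)
        with pytest.raises(ValueError, match="empty candidate"):
            select_lower_threshold(b, [])

    def test_resolution_scan_returns_grid_member(self):
        b = block_bipartite(3, n_blocks=2)
        gamma, scores = select_resolution(b, grid=(0.8, 1.0, 1.2), seed=0)
        assert gamma in (0.8, 1.0, 1.2)
        assert scores[gamma] == max(scores.values())


class TestCommunityExtraction:
    def test_grouping_and_ambiguity(self):
        ik = InteractionKey("X", 1, "Y")
        coll = {
            "p1": net("p1", {"X": 1, "Y": 1}, [("X", "Y", 1)]),
            "p2": net("p2", {"X": 1, "Y": -1}, [("X", "Y", 1)]),
        }
        inc = aggregate_networks(coll)
        b = build_bipartite(inc)
        part = louvain_bipartite(b, seed=0)
        results = extract_community_subgraphs(b, part, coll)
        [r] = results
        assert set(r.patients) == {"p1", "p2"}
        assert r.interactions == [ik]
        # Y appears active in p1 and inhibited in p2 -> 1 ambiguous / 2 genes
        assert r.ambiguity_fraction == pytest.approx(0.5)

    def test_single_state_community_zero_ambiguity(self):
        coll = {
            "p1": net("p1", {"X": 1, "Y": 1}, [("X", "Y", 1)]),
            "p2": net("p2", {"X": 1, "Y": 1}, [("X", "Y", 1)]),
        }
        b = build_bipartite(aggregate_networks(coll))
        part = louvain_bipartite(b, seed=0)
        [r] = extract_community_subgraphs(b, part, coll)
        assert r.ambiguity_fraction == 0.0
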