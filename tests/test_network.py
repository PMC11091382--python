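"""Network composition, precursor mapping and topology."""

import networkx as nx
import numpy as np
import pytest

from errmir.network import (
    Layer,
    NetworkCompositionError,
    compose_network,
    connected_pairs,
    map_to_mature,
    topology_stats,
)

from conftest import brute_force_join, make_network, random_regulation_layers, rec


class TestComposeNetwork:
    def test_minimal_join(self):
        net = compose_network([rec("a", "t1")], [rec("t1", "b", Layer.TF_TO_MIRNA)])
        assert net.edges == {("a", "b"): frozenset({"t1"})}

    def test_mediator_merging(self):
        net = compose_network(
            [rec("a", "t1"), rec("a", "t2")],
            [rec("t1", "b", Layer.TF_TO_MIRNA), rec("t2", "b", Layer.TF_TO_MIRNA)],
        )
        assert net.edges == {("a", "b"): frozenset({"t1", "t2"})}

    def test_self_loop_dropped(self):
        with pytest.raises(NetworkCompositionError):
            compose_network([rec("a", "t1")], [rec("t1", "a", Layer.TF_TO_MIRNA)])

    def test_empty_layer_rejected(self):
        with pytest.raises(NetworkCompositionError, match="no edges composable"):
            compose_network([], [rec("t1", "b", Layer.TF_TO_MIRNA)])

    def test_layer_mismatch_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            compose_network(
                [rec("a", "t1", Layer.TF_TO_MIRNA)],
                [rec("t1", "b", Layer.TF_TO_MIRNA)],
            )

    def test_ambiguous_identifier_warns_but_keeps(self, caplog):
        # "x" is both a miRNA regulator and a TF
        with caplog.at_level("WARNING"):
            net = compose_network(
                [rec("a", "x"), rec("x", "t1")],
                [rec("x", "b", Layer.TF_TO_MIRNA), rec("t1", "c", Layer.TF_TO_MIRNA)],
            )
        assert ("a", "b") in net.edges and ("x", "c") in net.edges
        assert "both miRNA and TF" in caplog.text

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_triple_join_oracle(self, seed):
        rng = np.random.default_rng(seed)
        l1, l2 = random_regulation_layers(rng, n_mirnas=30, n_tfs=10)
        expected = brute_force_join(l1, l2)
        if not expected:
            return
        net = compose_network(l1, l2)
        assert net.edges == expected

    def test_monotonicity_of_records(self):
        rng = np.random.default_rng(3)
        l1, l2 = random_regulation_layers(rng, n_mirnas=15, n_tfs=6, p1=0.3, p2=0.3)
        full = compose_network(l1, l2).edges
        reduced = compose_network(l1[:-3], l2).edges
        assert set(reduced) <= set(full)  # removing records never adds edges
        for k, tfs in reduced.items():
            assert tfs <= full[k]

    def test_co_target_mode(self):
        # a and b both regulate t1 -> connected both ways in co-target reading
        net = compose_network(
            [rec("a", "t1"), rec("b", "t1")],
            [rec("t1", "c", Layer.TF_TO_MIRNA)],
            join_mode="co_target",
        )
        assert set(net.edges) == {("a", "b"), ("b", "a")}


class TestMapToMature:
    def test_cross_product_expansion(self):
        net = make_network({("pre-x", "pre-y"): {"t"}})
        out = map_to_mature(net, {"pre-x": ["x-5p", "x-3p"], "pre-y": ["y-5p"]})
        assert set(out.edges) == {("x-5p", "y-5p"), ("x-3p", "y-5p")}
        assert all(tfs == frozenset({"t"}) for tfs in out.edges.values())

    def test_collapsed_edges_merge_mediators(self):
        net = make_network({("p1", "q"): {"t1"}, ("p2", "q"): {"t2"}})
        out = map_to_mature(net, {"p1": ["m"], "p2": ["m"], "q": ["n"]})
        assert out.edges == {("m", "n"): frozenset({"t1", "t2"})}

    def test_mature_ids_pass_through(self):
        net = make_network({("a-5p", "pre-b"): {"t"}})
        out = map_to_mature(net, {"pre-b": ["b-5p"]})
        assert set(out.edges) == {("a-5p", "b-5p")}

    def test_unmappable_precursor_drops_edge(self):
        net = make_network({("pre-a", "b"): {"t"}, ("c", "b"): {"t"}})
        out = map_to_mature(net, {}, precursors={"pre-a"})
        assert set(out.edges) == {("c", "b")}

    def test_expansion_self_loop_dropped(self):
        net = make_network({("pre-a", "m"): {"t"}})
        out = map_to_mature(net, {"pre-a": ["m", "m2"]})
        assert set(out.edges) == {("m2", "m")}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_expand_then_dedupe_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"p{i}" for i in range(12)]
        edges = {}
        for _ in range(25):
            a, b = rng.choice(nodes, size=2, replace=False)
            edges.setdefault((a, b), set()).add(f"t{rng.integers(5)}")
        pmap = {
            p: [f"{p}m{k}" for k in range(rng.integers(1, 3))]
            for p in nodes
            if rng.random() < 0.7
        }
        net = make_network(edges)
        out = map_to_mature(net, pmap)

        oracle: dict[tuple[str, str], set[str]] = {}
        for (a, b), tfs in net.edges.items():
            for ma in pmap.get(a, [a]):
                for mb in pmap.get(b, [b]):
                    if ma != mb:
                        oracle.setdefault((ma, mb), set()).update(tfs)
        assert out.edges == {k: frozenset(v) for k, v in oracle.items()}

    def test_mediator_multiset_conserved(self):
        net = make_network({("pre-a", "pre-b"): {"t1", "t2"}})
        out = map_to_mature(net, {"pre-a": ["a1", "a2"], "pre-b": ["b1"]})
        for tfs in out.edges.values():
            assert tfs == frozenset({"t1", "t2"})


class TestTopology:
    def test_star_graph(self):
        net = make_network({("hub", f"leaf{i}"): {"t"} for i in range(4)})
        rep = topology_stats(net)
        assert rep.degree_histogram == {4: 1, 1: 4}
        assert rep.avg_clustering == 0.0
        assert rep.n_nodes == 5 and rep.n_edges == 4

    def test_clique(self):
        nodes = ["a", "b", "c", "d"]
        net = make_network(
            {(x, y): {"t"} for x in nodes for y in nodes if x < y}
        )
        rep = topology_stats(net)
        assert rep.avg_clustering == pytest.approx(1.0)
        assert rep.avg_shortest_path == pytest.approx(1.0)

    def test_path_length_matches_bfs_oracle(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(50)]
        edges = {}
        for _ in range(120):
            a, b = rng.choice(nodes, size=2, replace=False)
            edges[(a, b)] = {"t"}
        net = make_network(edges)
        rep = topology_stats(net)

        g = net.to_networkx().to_undirected()
        comp = max(nx.connected_components(g), key=len)
        # plain BFS all-pairs average on the largest component
        total, pairs = 0, 0
        comp = sorted(comp)
        adj = {n: set(g.neighbors(n)) for n in comp}
        for src in comp:
            dist = {src: 0}
            frontier = [src]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            nxt.append(v)
                frontier = nxt
            for tgt in comp:
                if tgt != src:
                    total += dist[tgt]
                    pairs += 1
        assert rep.avg_shortest_path == pytest.approx(total / pairs)

    def test_degree_histogram_sums_to_nodes(self, small_study):
        rep = topology_stats(small_study.network)
        assert sum(rep.degree_histogram.values()) == rep.n_nodes
        assert 0.0 <= rep.avg_clustering <= 1.0

    def test_single_node_no_path(self):
        net = make_network({})
        net.nodes = {"only"}
        rep = topology_stats(net)
        assert rep.avg_shortest_path is None


class TestConnectedPairs:
    def test_identity_and_empty(self):
        net = make_network({("a", "b"): {"t"}, ("b", "c"): {"u"}})
        assert len(connected_pairs(net, net.nodes)) == 2
        assert connected_pairs(net, set()) == []

    def test_sorted_deterministically(self):
        net = make_network({("b", "c"): {"t"}, ("a", "b"): {"t"}, ("a", "c"): {"t"}})
        pairs = [(a, b) for a, b, _ in connected_pairs(net, net.nodes)]
        assert pairs == sorted(pairs)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_filter_oracle(self, seed, small_study):
        rng = np.random.default_rng(seed)
        nodes = sorted(small_study.network.nodes)
        retained = {n for n in nodes if rng.random() < 0.5}
        got = {(a, b) for a, b, _ in connected_pairs(small_study.network, retained)}
        expected = {
            (a, b)
            for (a, b) in small_study.network.edges
            if a in retained and b in retained
        }
        assert got == expected
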