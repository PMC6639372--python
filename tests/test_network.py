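import math

import networkx as nx
import numpy as np
import pytest

from oracles import brute_betweenness, floyd_warshall, katz_series
from targetnet import (
    GeneClassCatalog,
    centralities,
    class_distance_summary,
    group_distance_analysis,
    load_network,
    neighbor_class_ratios,
)
from targetnet.network import (
    InteractionNetwork,
    all_class_distances,
    all_neighbor_ratios,
    from_edges,
)


def random_net(n=30, p=0.15, seed=0):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return InteractionNetwork(
        nx.relabel_nodes(g, {i: f"N{i:02d}" for i in range(n)})
    )


class TestLoadNetwork:
    def test_duplicates_and_self_loops_removed(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\nB\tA\nA\tA\n")
        net = load_network(path)
        assert net.n_nodes == 2 and net.n_edges == 1

    def test_directed_keeps_both_orientations(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\nB\tA\n")
        net = load_network(path, directed=True)
        assert net.n_nodes == 2 and net.n_edges == 2

    def test_biogrid_tab3_column_map(self, tmp_path):
        # tab3-style: official symbols live in columns 7 and 8
        header = "\t".join(f"col{i}" for i in range(12))
        rows = []
        pairs = [("TP53", "MDM2"), ("TP53", "EP300"), ("EGFR", "GRB2"),
                 ("EGFR", "GRB2"), ("KRAS", "RAF1"), ("RAF1", "MAP2K1"),
                 ("MYC", "MAX"), ("MAX", "MYC"), ("AKT1", "AKT1"),
                 ("CTNNB1", "APC")]
        for a, b in pairs:
            fields = [f"x{i}" for i in range(12)]
            fields[7], fields[8] = a, b
            rows.append("\t".join(fields))
        path = tmp_path / "biogrid.tab3.txt"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        net = load_network(path, column_map={"source": 7, "target": 8},
                           skip_header=True)
        # hand count: 10 rows, one duplicate, one symmetric duplicate,
        # one self-loop -> 7 edges over 13 distinct non-loop genes
        assert net.n_edges == 7
        assert net.n_nodes == 13

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\tB\nJUSTONE\n")
        with pytest.raises(ValueError, match=":2:"):
            load_network(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("# nothing\n")
        with pytest.raises(ValueError, match="empty"):
            load_network(path)

    def test_sign_column_preserved(self, tmp_path):
        path = tmp_path / "signed.tsv"
        path.write_text("A\tB\tpositive\nB\tC\tnegative\n")
        net = load_network(path, directed=True, sign_column=2)
        assert net.graph.edges["A", "B"]["sign"] == "positive"


class TestCentralities:
    def test_path_graph_betweenness(self):
        net = from_edges([("A", "B"), ("B", "C")])
        c = centralities(net, measures=("betweenness",))
        assert c.loc["B", "betweenness"] == 1.0
        assert c.loc["A", "betweenness"] == 0.0

    def test_star_center_degree_and_closeness(self):
        net = from_edges([("C", f"L{i}") for i in range(4)])
        c = centralities(net, measures=("degree", "closeness"))
        assert c.loc["C", "degree"] == 1.0
        assert c.loc["C", "closeness"] == 1.0

    def test_betweenness_matches_path_enumeration_oracle(self):
        net = random_net(seed=1)
        c = centralities(net, measures=("betweenness",))
        oracle = brute_betweenness(list(net.graph.edges), list(net.nodes))
        for node in net.nodes:
            assert c.loc[node, "betweenness"] == pytest.approx(oracle[node], abs=1e-9)

    def test_katz_matches_truncated_power_series(self):
        net = random_net(seed=2)
        c = centralities(net, measures=("katz",))
        a = nx.to_numpy_array(net.graph)
        lam = max(abs(np.linalg.eigvals(a)))
        oracle = katz_series(list(net.graph.edges), list(net.nodes),
                             alpha=0.9 / lam.real)
        np.testing.assert_allclose(
            c.katz.to_numpy(), oracle, rtol=1e-5
        )

    def test_degree_sum_invariants(self):
        net = random_net(seed=3)
        degs = [net.graph.degree(n) for n in net.nodes]
        assert sum(degs) == 2 * net.n_edges
        dg = nx.gnp_random_graph(20, 0.2, seed=4, directed=True)
        dnet = InteractionNetwork(dg)
        assert sum(d for _, d in dg.in_degree) == dnet.n_edges
        assert sum(d for _, d in dg.out_degree) == dnet.n_edges

    def test_in_out_degree_require_directed(self):
        with pytest.raises(ValueError, match="directed"):
            centralities(from_edges([("A", "B")]), measures=("in_degree",))

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            centralities(from_edges([("A", "B")]), measures=("harmonic",))

    def test_centrality_rank_correlations_positive(self):
        """Katz/eigenvector track closeness/degree on scale-free graphs."""
        from scipy.stats import spearmanr

        g = nx.barabasi_albert_graph(150, 3, seed=5)
        net = InteractionNetwork(nx.relabel_nodes(g, {i: f"N{i}" for i in g}))
        c = centralities(
            net, measures=("degree", "closeness", "pagerank", "eigenvector", "katz")
        )
        assert spearmanr(c.degree, c.pagerank).statistic > 0.5
        assert spearmanr(c.closeness, c.eigenvector).statistic > 0.5
        assert spearmanr(c.closeness, c.katz).statistic > 0.5


class TestClassDistances:
    def test_adjacent_singleton_target(self):
        net = from_edges([("A", "B"), ("B", "C")])
        assert class_distance_summary(net, "A", {"B"}) == (1.0, 1.0)

    def test_self_only_target_gives_sentinel(self):
        net = from_edges([("A", "B")])
        sent = float(net.default_sentinel)
        assert class_distance_summary(net, "A", {"A"}, exclude_self=True) == (sent, sent)

    def test_unreachable_target_gives_sentinel(self):
        net = from_edges([("A", "B"), ("C", "D")])
        sent = float(net.default_sentinel)
        assert class_distance_summary(net, "A", {"C", "D"}) == (sent, sent)

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            class_distance_summary(from_edges([("A", "B")]), "Z", {"A"})

    def test_matches_floyd_warshall_oracle(self):
        net = random_net(n=50, p=0.08, seed=6)
        rng = np.random.default_rng(6)
        nodes = list(net.nodes)
        target = set(rng.choice(nodes, size=5, replace=False))
        apsp = floyd_warshall(list(net.graph.edges), nodes)
        for node in nodes:
            avg, mn = class_distance_summary(net, node, target)
            dists = [
                apsp[(node, t)]
                for t in target
                if t != node and not math.isinf(apsp[(node, t)])
            ]
            if dists:
                assert avg == pytest.approx(np.mean(dists))
                assert mn == min(dists)
            else:
                assert avg == mn == float(net.default_sentinel)

    def test_bulk_distances_agree_with_per_node_summary(self, small_dataset):
        ds = small_dataset
        from targetnet.catalog import node_type_sets

        table = all_class_distances(ds.network, ds.catalog)
        sets = node_type_sets(ds.catalog, ds.network)
        rng = np.random.default_rng(0)
        for node in rng.choice(list(ds.network.nodes), size=12, replace=False):
            for label in ("DTG", "PFG", "OG"):
                avg, mn = class_distance_summary(ds.network, node, sets[label])
                assert table.loc[node, f"dist_{label}_avg"] == pytest.approx(avg)
                assert table.loc[node, f"dist_{label}_min"] == pytest.approx(mn)

    def test_min_not_above_avg_where_finite(self, small_dataset):
        ds = small_dataset
        table = all_class_distances(ds.network, ds.catalog)
        sent = ds.network.default_sentinel
        for label in ("DTG", "DAG", "OG"):
            avg = table[f"dist_{label}_avg"]
            mn = table[f"dist_{label}_min"]
            finite = (avg < sent) & (mn < sent)
            assert (mn[finite] <= avg[finite] + 1e-12).all()

    def test_directed_distances_follow_edge_direction(self):
        net = from_edges([("A", "B"), ("B", "C")], directed=True)
        assert class_distance_summary(net, "A", {"C"}) == (2.0, 2.0)
        sent = float(net.default_sentinel)
        assert class_distance_summary(net, "C", {"A"}) == (sent, sent)


class TestNeighborRatios:
    def test_half_labeled_neighbors(self):
        net = from_edges([("X", n) for n in "ABCD"])
        catalog = GeneClassCatalog(members={"DTG": {"A", "B"}})
        ratios = neighbor_class_ratios(net, "X", catalog)
        assert ratios["DTG"] == 0.5
        assert ratios["OG"] == 0.5

    def test_all_unlabeled_neighbors(self):
        net = from_edges([("X", "A"), ("X", "B")])
        ratios = neighbor_class_ratios(net, "X", GeneClassCatalog())
        assert ratios["OG"] == 1.0
        assert sum(ratios[lbl] for lbl in ("DTG", "DAG", "PFG", "PUG", "URG", "DRG")) == 0

    def test_multilabel_neighbor_counted_in_both(self):
        net = from_edges([("X", "A"), ("X", "B")])
        catalog = GeneClassCatalog(members={"DTG": {"A"}, "PUG": {"A"}})
        ratios = neighbor_class_ratios(net, "X", catalog)
        assert ratios["DTG"] == ratios["PUG"] == 0.5
        assert sum(ratios.values()) >= 1.0

    def test_bulk_ratios_match_counting_oracle(self, small_dataset):
        ds = small_dataset
        from targetnet.catalog import node_type_sets

        table = all_neighbor_ratios(ds.network, ds.catalog)
        sets = node_type_sets(ds.catalog, ds.network)
        rng = np.random.default_rng(1)
        for node in rng.choice(list(ds.network.nodes), size=15, replace=False):
            nbrs = set(ds.network.graph.neighbors(node))
            for label, members in sets.items():
                expected = len(nbrs & members) / len(nbrs)
                assert table.loc[node, f"ratio_{label}"] == pytest.approx(expected)


class TestGroupDistance:
    def test_planted_embedding_detected_as_closer(self):
        # class A genes wired directly into class B's neighborhood, OG far
        edges = []
        for i in range(12):
            edges.append((f"A{i}", f"B{i}"))
            edges.append((f"B{i}", "HUB"))
        chain = ["HUB"] + [f"O{i}" for i in range(30)]
        edges += list(zip(chain[:-1], chain[1:]))
        net = from_edges(edges)
        catalog = GeneClassCatalog(
            members={
                "DTG": {f"A{i}" for i in range(12)},
                "DAG": {f"B{i}" for i in range(12)},
            }
        )
        res = group_distance_analysis(net, catalog, "DTG", "DAG")
        assert res.direction == "closer"
        assert res.p_value_avg < 0.01

    def test_background_vs_itself_is_null(self, small_dataset):
        ds = small_dataset
        res = group_distance_analysis(ds.network, ds.catalog, "DTG", "OG")
        assert res.p_value_avg > 0.9

    def test_singleton_classes_distance_matches_bfs(self):
        net = from_edges([("A", "M"), ("M", "B"), ("B", "O1"), ("O1", "O2")])
        catalog = GeneClassCatalog(members={"DTG": {"A"}, "DAG": {"B"}})
        res = group_distance_analysis(net, catalog, "DTG", "DAG")
        assert res.per_node.loc["A", "avg_to_class"] == 2.0
        assert res.per_node.loc["A", "min_to_class"] == 2.0

    def test_empty_class_rejected(self, small_dataset):
        ds = small_dataset
        catalog = GeneClassCatalog(members={"DTG": set(ds.catalog["DTG"])})
        with pytest.raises(ValueError, match="empty"):
            group_distance_analysis(ds.network, catalog, "DTG", "DAG")
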