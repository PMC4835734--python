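import networkx as nx
import numpy as np
import pytest

import sirthresh as st
from sirthresh.netio import UndefinedMetricError


class TestReadEdgeList:
    def write(self, tmp_path, lines):
        p = tmp_path / "net.edges"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_dedup_selfloop_weight_rules(self, tmp_path):
        p = self.write(tmp_path, ["0 1", "1 0", "1 1", "1 2 0.7"])
        net = st.read_edge_list(p)
        assert net.n_nodes == 3
        assert net.edge_set() == {(0, 1), (1, 2)}

    def test_cycle_file(self, tmp_path, cycle6):
        p = tmp_path / "c6.edges"
        cycle6.write_edge_list(p)
        net = st.read_edge_list(p)
        assert (net.n_nodes, net.n_edges) == (6, 6)

    def test_string_labels_relabeled(self, tmp_path):
        p = self.write(tmp_path, ["a b", "b c"])
        net = st.read_edge_list(p)
        assert net.n_nodes == 3
        assert net.labels == ["a", "b", "c"]
        assert net.edge_set() == {(0, 1), (1, 2)}

    def test_comments_and_blank_lines(self, tmp_path):
        p = self.write(tmp_path, ["# header", "", "0 1", "# mid", "1 2"])
        assert st.read_edge_list(p).n_edges == 2

    def test_malformed_line_reports_number(self, tmp_path):
        p = self.write(tmp_path, ["0 1", "7"])
        with pytest.raises(ValueError, match="line 2"):
            st.read_edge_list(p)

    def test_empty_file(self, tmp_path):
        p = self.write(tmp_path, ["# only comments"])
        with pytest.raises(ValueError, match="empty"):
            st.read_edge_list(p)


class TestGiantComponent:
    def test_tie_breaks_to_smallest_label(self):
        # two disjoint triangles: {0,1,2} and {3,4,5}
        net = st.Network(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        giant = st.giant_component(net)
        assert giant.n_nodes == 3
        assert giant.labels is None  # kept nodes 0,1,2 in place

    def test_connected_graph_unchanged(self, regular_4_10):
        assert st.giant_component(regular_4_10) == regular_4_10

    def test_edgeless_graph_single_node(self):
        net = st.Network(5, [])
        assert st.giant_component(net).n_nodes == 1

    def test_output_connected(self, small_config_net):
        g = st.giant_component(small_config_net).to_networkx()
        assert nx.is_connected(g)


class TestDegreeStats:
    def test_regular(self, regular_4_10):
        s = st.degree_stats(regular_4_10)
        assert (s.mean_k, s.mean_k2) == (4.0, 16.0)

    def test_star(self, star4):
        s = st.degree_stats(star4)
        assert s.mean_k == pytest.approx(8 / 5)
        assert s.mean_k2 == pytest.approx(4.0)

    def test_k2(self):
        s = st.degree_stats(st.Network(2, [(0, 1)]))
        assert (s.mean_k, s.mean_k2) == (1.0, 1.0)

    def test_jensen_on_random_nets(self, small_config_net):
        s = st.degree_stats(small_config_net)
        assert s.mean_k2 >= s.mean_k**2


class TestAssortativity:
    def test_regular_undefined(self, regular_4_10):
        with pytest.raises(UndefinedMetricError):
            st.assortativity(regular_4_10)

    def test_path4_exact(self, path4):
        # brute-force Pearson over the 6 oriented endpoint pairs gives -1/2
        assert st.assortativity(path4) == pytest.approx(-0.5)

    def test_matches_networkx(self, small_config_net):
        ours = st.assortativity(small_config_net)
        theirs = nx.degree_assortativity_coefficient(
            small_config_net.to_networkx())
        assert ours == pytest.approx(theirs, rel=1e-8)

    def test_range(self, small_config_net, star4, path4):
        for net in (small_config_net, path4):
            assert -1.0 <= st.assortativity(net) <= 1.0


class TestClusteringModularityKcore:
    def test_triangle_clustering(self, triangle):
        assert st.clustering(triangle) == 1.0

    def test_tree_clustering_zero(self, star4):
        assert st.clustering(star4) == 0.0

    def test_k4_minus_edge(self):
        # exhaustive: two degree-3 nodes have 2 of 3 neighbor pairs linked,
        # two degree-2 nodes have their single neighbor pair linked
        net = st.Network(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])
        assert st.clustering(net) == pytest.approx((2 / 3 + 2 / 3 + 1 + 1) / 4)

    def test_two_cliques_modularity(self, two_cliques):
        # evaluating Q on the two-clique split lower-bounds the greedy value
        g = two_cliques.to_networkx()
        q_split = nx.community.modularity(g, [set(range(5)), set(range(5, 10))])
        res = st.modularity(two_cliques)
        assert res.Q >= q_split > 0.3

    def test_complete_graph_q_near_zero(self):
        res = st.modularity(st.fixture("clique", N=6))
        assert abs(res.Q) < 1e-9

    def test_modularity_deterministic(self, two_cliques):
        assert st.modularity(two_cliques).Q == st.modularity(two_cliques).Q

    @pytest.mark.parametrize(
        "builder,expected",
        [
            (lambda: st.fixture("star", n=5), 1),
            (lambda: st.fixture("clique", N=5), 4),
        ],
    )
    def test_max_kcore(self, builder, expected):
        assert st.max_kcore(builder()) == expected

    def test_kcore_clique_with_pendant(self):
        net = st.Network(5, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
                             (3, 4)])
        assert st.max_kcore(net) == 3


def test_metrics_row_columns(small_config_net):
    row = st.netio.metrics_row("cfg", small_config_net)
    assert list(row.columns) == ["name", "N", "E", "mean_k", "mean_k2",
                                 "kmax", "r", "c", "Q", "kcore_max"]
    assert row.loc[0, "N"] == small_config_net.n_nodes
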