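import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from roiflow import netprop
from roiflow.enrich import EnrichmentRow
from roiflow.errors import ConfigurationError, ParseError
from roiflow.netprop import PpiNetwork

from oracles import betweenness_enumeration_oracle, random_connected_graph


def path_graph(*nodes):
    return PpiNetwork.from_edges(list(zip(nodes, nodes[1:])))


def deg_table(lfc: dict, is_deg: bool = True):
    idx = list(lfc)
    return pd.DataFrame(
        {"log2fc": [lfc[g] for g in idx], "adj_p": 0.01, "p": 0.001,
         "base_mean": 10.0, "se": 0.1, "wald_stat": 1.0,
         "is_deg": is_deg, "direction": "up", "converged": True},
        index=idx,
    )


class TestReadNetwork:
    def test_dedup_and_self_loop_drop(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("A\tB\nB\tA\nA\tA\n")
        net = netprop.read_network(path)
        assert set(net.graph.edges) == {("A", "B")}

    def test_empty_file_empty_network(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        net = netprop.read_network(path)
        assert net.n_nodes == 0
        with pytest.raises(ConfigurationError):
            net.column_normalize()
        with pytest.raises(ConfigurationError):
            netprop.betweenness(net)

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\tB\nJUSTONE\n")
        with pytest.raises(ParseError, match=":2"):
            netprop.read_network(path)

    def test_biogrid_tab3_fixture(self, tmp_path):
        path = tmp_path / "biogrid.tab3.txt"
        header = "\t".join(
            ["#BioGRID Interaction ID", "Entrez Gene Interactor A",
             "Entrez Gene Interactor B", "Official Symbol Interactor A",
             "Official Symbol Interactor B", "Experimental System"])
        rows = [
            "1\t100\t200\tSnca\tTubb2a\tTwo-hybrid",
            "2\t100\t300\tSNCA\tLAMP1\tAP-MS",
            "3\t200\t300\tTUBB2A\tLAMP1\tAP-MS",
        ]
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        net = netprop.read_network(path, format="biogrid_tab3")
        # symbols upper-cased, 3 nodes, 3 edges
        assert set(net.graph.nodes) == {"SNCA", "TUBB2A", "LAMP1"}
        assert net.n_edges == 3

    def test_unknown_format(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("A\tB\n")
        with pytest.raises(ConfigurationError):
            netprop.read_network(path, format="weird")


class TestColumnNormalize:
    def test_path_graph_middle_column(self):
        net = path_graph("A", "B", "C")
        w = net.column_normalize().toarray()
        order = net.node_order
        j = order.index("B")
        col = {order[i]: w[i, j] for i in range(3)}
        assert col == {"A": 0.5, "B": 0.0, "C": 0.5}

    def test_columns_sum_to_one(self):
        net = PpiNetwork.from_graph(nx.erdos_renyi_graph(30, 0.2, seed=1))
        w = net.column_normalize()
        sums = np.asarray(w.sum(axis=0)).ravel()
        degrees = [net.graph.degree(v) for v in net.node_order]
        for s, d in zip(sums, degrees):
            assert s == pytest.approx(1.0 if d > 0 else 0.0, abs=1e-12)

    def test_star_center_column(self):
        net = PpiNetwork.from_edges([("C", "L1"), ("C", "L2"), ("C", "L3")])
        w = net.column_normalize().toarray()
        order = net.node_order
        j = order.index("C")
        for leaf in ("L1", "L2", "L3"):
            assert w[order.index(leaf), j] == pytest.approx(1 / 3)


class TestInitializeSeed:
    def test_two_genes_proportional(self):
        net = path_graph("A", "B", "C")
        p0 = netprop.initialize_seed(deg_table({"A": 1.0, "B": 3.0}), net)
        assert p0["A"] == pytest.approx(0.25)
        assert p0["B"] == pytest.approx(0.75)
        assert p0["C"] == 0.0

    def test_equal_lfc_uniform(self):
        net = path_graph("A", "B", "C")
        p0 = netprop.initialize_seed(
            deg_table({"A": -1.0, "B": 1.0, "C": 1.0}), net)
        np.testing.assert_allclose(p0.to_numpy(), [1 / 3, 1 / 3, 1 / 3])

    def test_single_mapped_gene(self):
        net = path_graph("A", "B")
        p0 = netprop.initialize_seed(deg_table({"A": 2.0, "ZZZ": 5.0}), net)
        assert p0["A"] == 1.0

    def test_no_mapped_gene_rejected(self):
        net = path_graph("A", "B")
        with pytest.raises(ConfigurationError):
            netprop.initialize_seed(deg_table({"X": 1.0}), net)

    def test_signed_positive_floors_negatives(self):
        net = path_graph("A", "B", "C")
        p0 = netprop.initialize_seed(
            deg_table({"A": -1.0, "B": 3.0}), net, mode="signed_positive")
        assert p0["A"] == 0.0
        assert p0["B"] == 1.0

    def test_all_negative_signed_rejected(self):
        net = path_graph("A", "B")
        with pytest.raises(ConfigurationError):
            netprop.initialize_seed(deg_table({"A": -1.0}), net,
                                    mode="signed_positive")


class TestRwr:
    def test_restart_one_returns_seed(self):
        net = path_graph("A", "B", "C")
        p0 = np.array([1.0, 0.0, 0.0])
        out = netprop.rwr(net.column_normalize(), p0, r=1.0)
        np.testing.assert_allclose(out, p0)

    def test_two_node_closed_form(self):
        # (I - 0.5 W') p = 0.5 p0 on a single edge gives (2/3, 1/3)
        net = path_graph("A", "B")
        p0 = np.array([1.0, 0.0])
        for method in ("iterative", "exact"):
            out = netprop.rwr(net.column_normalize(), p0, r=0.5, method=method)
            np.testing.assert_allclose(out, [2 / 3, 1 / 3], atol=1e-7)

    def test_iterative_agrees_with_exact(self, rng):
        for _ in range(10):
            g = random_connected_graph(rng, n_max=40)
            net = PpiNetwork.from_graph(g)
            w = net.column_normalize()
            p0 = rng.random(net.n_nodes)
            p0 /= p0.sum()
            it = netprop.rwr(w, p0, r=0.4, tol=1e-10, method="iterative")
            ex = netprop.rwr(w, p0, r=0.4, method="exact")
            assert np.abs(it - ex).sum() < 1e-7

    def test_fixed_point_satisfies_equation(self, rng):
        g = random_connected_graph(rng, n_max=30)
        net = PpiNetwork.from_graph(g)
        w = net.column_normalize()
        p0 = rng.random(net.n_nodes)
        p0 /= p0.sum()
        p = netprop.rwr(w, p0, r=0.5, tol=1e-12)
        residual = p - (0.5 * (w @ p) + 0.5 * p0)
        assert np.abs(residual).max() < 1e-8

    def test_mass_conserved(self, rng):
        g = random_connected_graph(rng, n_max=50)
        net = PpiNetwork.from_graph(g)
        p = netprop.rwr(net.column_normalize(),
                        np.full(net.n_nodes, 1 / net.n_nodes), r=0.3)
        assert p.sum() == pytest.approx(1.0, abs=1e-10)
        assert (p >= 0).all()

    def test_invalid_restart_rate(self):
        net = path_graph("A", "B")
        with pytest.raises(ConfigurationError):
            netprop.rwr(net.column_normalize(), np.array([1.0, 0.0]), r=0.0)

    def test_non_convergence_raises(self):
        net = path_graph("A", "B", "C", "D")
        with pytest.raises(ConfigurationError, match="converge"):
            netprop.rwr(net.column_normalize(), np.array([1.0, 0, 0, 0]),
                        r=0.01, tol=1e-15, max_iter=2)

    def test_monotone_seed_influence(self):
        # raising a node's seed mass never lowers its steady-state mass
        net = path_graph("A", "B", "C", "D")
        w = net.column_normalize()
        i = net.node_order.index("B")
        masses = []
        for extra in (0.0, 0.2, 0.4):
            p0 = np.full(4, (1 - extra) / 4)
            p0[i] += extra
            p0 /= p0.sum()
            masses.append(netprop.rwr(w, p0, r=0.5, tol=1e-12)[i])
        assert masses[0] <= masses[1] <= masses[2]


class TestBetweenness:
    def test_path_graph(self):
        bc = netprop.betweenness(path_graph("A", "B", "C"))
        assert bc["B"] == pytest.approx(2.0)  # ordered pairs A->C and C->A
        assert bc["A"] == bc["C"] == 0.0

    def test_star_graph(self):
        net = PpiNetwork.from_edges([("C", "L1"), ("C", "L2"), ("C", "L3")])
        bc = netprop.betweenness(net)
        assert bc["C"] == pytest.approx(6.0)  # 3 * 2 ordered leaf pairs
        assert bc[["L1", "L2", "L3"]].eq(0).all()

    def test_complete_graph_all_zero(self):
        net = PpiNetwork.from_graph(nx.complete_graph(4))
        assert netprop.betweenness(net).eq(0).all()

    def test_tree_leaves_zero(self):
        net = PpiNetwork.from_graph(nx.random_labeled_tree(12, seed=4))
        bc = netprop.betweenness(net)
        for v in net.node_order:
            if net.graph.degree(v) == 1:
                assert bc[v] == 0.0

    def test_disconnected_pairs_contribute_zero(self):
        net = PpiNetwork.from_edges([("A", "B"), ("B", "C"), ("X", "Y")])
        bc = netprop.betweenness(net)
        assert bc["B"] == pytest.approx(2.0)
        assert bc["X"] == bc["Y"] == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, seed):
        g = random_connected_graph(np.random.default_rng(seed), n_max=8)
        net = PpiNetwork.from_graph(g)
        bc = netprop.betweenness(net)
        oracle = betweenness_enumeration_oracle(g)
        for v in net.node_order:
            assert bc[v] == pytest.approx(oracle[v], abs=1e-9)


def enrichment_rows(term_genes: dict, adj_p=0.01):
    return [
        EnrichmentRow(term=t, k=len(g), K=len(g), n=10, p=adj_p / 2,
                      adj_p=adj_p, odds_ratio=2.0, combined_score=3.0,
                      genes=sorted(g))
        for t, g in term_genes.items()
    ]


class TestSelectKeyGenes:
    def test_brute_force_set_arithmetic(self, rng):
        genes = [f"G{i:02d}" for i in range(25)]
        prob = pd.Series(rng.permutation(25).astype(float) + 1, index=genes)
        bc = pd.Series(0.0, index=genes)
        top20 = set(prob.sort_values(ascending=False).index[:20])
        pathway = set(rng.choice(sorted(top20), size=4, replace=False)) | set(
            rng.choice(sorted(set(genes) - top20), size=3, replace=False))
        # pathway genes outside top-20 must not appear
        rows = enrichment_rows({"T": pathway})
        report = netprop.select_key_genes(prob, bc, rows, top_n=20)
        assert set(report.key_genes) == pathway & top20
        assert len(pathway & top20) == 4

    def test_top_n_exceeding_gene_count(self):
        prob = pd.Series({"A": 0.5, "B": 0.3, "C": 0.2})
        bc = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0})
        rows = enrichment_rows({"T": {"B", "C", "Z"}})
        report = netprop.select_key_genes(prob, bc, rows, top_n=10)
        assert report.top == ["A", "B", "C"]
        assert report.key_genes == ["B", "C"]

    def test_probability_tie_broken_by_betweenness(self):
        prob = pd.Series({"A": 0.5, "B": 0.5, "C": 0.0})
        bc = pd.Series({"A": 1.0, "B": 5.0, "C": 0.0})
        report = netprop.select_key_genes(prob, bc, enrichment_rows({}), top_n=1)
        assert report.top == ["B"]

    def test_full_tie_broken_lexicographically(self):
        prob = pd.Series({"B": 0.5, "A": 0.5})
        bc = pd.Series({"B": 1.0, "A": 1.0})
        report = netprop.select_key_genes(prob, bc, [], top_n=2)
        assert report.top == ["A", "B"]

    def test_empty_enrichment_warns_empty_key_genes(self, caplog):
        prob = pd.Series({"A": 1.0})
        bc = pd.Series({"A": 0.0})
        with caplog.at_level("WARNING"):
            report = netprop.select_key_genes(prob, bc, [])
        assert report.key_genes == []
        assert any("empty enrichment" in r.message for r in caplog.records)

    def test_insignificant_rows_excluded(self):
        prob = pd.Series({"A": 1.0, "B": 0.5})
        bc = pd.Series(0.0, index=["A", "B"])
        rows = enrichment_rows({"T": {"A", "B"}}, adj_p=0.2)
        report = netprop.select_key_genes(prob, bc, rows)
        assert report.key_genes == []
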