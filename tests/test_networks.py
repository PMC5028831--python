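import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from txpipe.networks import (
    Network,
    RelationTable,
    bh_fdr,
    coexpression_network,
    correlation_table,
    gene_act_network,
    kcore_decompose,
    pathway_act_network,
)


def rel(rows):
    return RelationTable(pd.DataFrame(rows, columns=["src", "dst", "type"]))


def brute_force_cores(g: nx.Graph) -> dict:
    """Oracle: for each k, repeatedly delete nodes with degree < k."""
    cores = {n: 0 for n in g.nodes}
    k = 1
    while True:
        h = g.copy()
        changed = True
        while changed:
            low = [n for n in h.nodes if h.degree(n) < k]
            changed = bool(low)
            h.remove_nodes_from(low)
        if h.number_of_nodes() == 0:
            break
        for n in h.nodes:
            cores[n] = k
        k += 1
    return cores


class TestRelationTable:
    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="unknown relation"):
            rel([("a", "b", "hugs")])

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            rel([("a", "a", "activation")])


class TestPathwayActNetwork:
    def test_empty_relations(self):
        net = pathway_act_network({"A", "B"}, rel([]))
        assert net.n_nodes == 2 and net.n_edges == 0

    def test_hand_degree(self):
        net = pathway_act_network(
            {"A", "B", "C"},
            rel([("A", "B", "activation"), ("A", "C", "activation")]))
        assert net.degrees()["A"] == 2
        assert net.central_nodes() == ["A"]

    def test_induced_subgraph_property(self):
        relations = rel([("A", "B", "activation"), ("A", "X", "inhibition"),
                         ("X", "Y", "binding/association")])
        a = pathway_act_network({"A", "B"}, relations)
        b = pathway_act_network({"A", "B"}, rel([("A", "B", "activation")]))
        assert set(a.graph.edges) == set(b.graph.edges)


class TestGeneActNetwork:
    def test_endpoint_filtering(self):
        relations = rel([("g1", "g2", "activation"), ("g1", "gX", "inhibition"),
                         ("g2", "g3", "compound")])
        net = gene_act_network({"g1": "up", "g2": "down", "g3": "up"}, relations)
        assert net.n_edges == 2

    def test_no_degs_empty(self):
        net = gene_act_network({}, rel([("a", "b", "activation")]))
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_types_and_directions_preserved(self):
        net = gene_act_network({"a": "up", "b": "down"},
                               rel([("a", "b", "phosphorylation")]))
        assert net.graph.edges["a", "b"]["type"] == "phosphorylation"
        assert net.graph.nodes["a"]["direction"] == "up"


class TestCoexpression:
    def test_duplicated_gene_positive_edge(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 8)
        values = np.vstack([base, base, rng.normal(0, 1, 8)])
        net = coexpression_network(values, ["g1", "g2", "g3"], fdr_threshold=0.05)
        assert net.graph.has_edge("g1", "g2")
        assert net.graph.edges["g1", "g2"]["sign"] == "positive"
        assert net.graph.edges["g1", "g2"]["r"] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        values = np.array([[1.0, 2, 3, 4], [8.0, 6, 4, 2], [1.0, 2, 1.5, 3]])
        tab = correlation_table(values, ["x", "y", "z"])
        row = tab[(tab["gene_a"] == "x") & (tab["gene_b"] == "y")].iloc[0]
        assert row["r"] == pytest.approx(-1.0)
        net = coexpression_network(values, ["x", "y", "z"], fdr_threshold=0.05)
        assert net.graph.edges["x", "y"]["sign"] == "negative"

    def test_n3_feasibility_bound(self):
        # with 3 samples (df=1) raw p < 0.05 needs |r| > 0.997
        t_crit = stats.t.ppf(1 - 0.025, df=1)
        assert t_crit == pytest.approx(12.706, abs=1e-3)
        r_min = t_crit / np.sqrt(1 + t_crit**2)
        assert r_min == pytest.approx(0.997, abs=5e-4)

        def p_of(r):
            t = r * np.sqrt(1 / (1 - r**2))
            return 2 * stats.t.sf(abs(t), df=1)

        assert p_of(0.9975) < 0.05 < p_of(0.996)

    def test_zero_variance_gene_excluded(self):
        values = np.array([[1.0, 1, 1, 1], [1.0, 2, 3, 4], [4.0, 3, 2, 1]])
        tab = correlation_table(values, ["flat", "a", "b"])
        assert "flat" not in set(tab["gene_a"]) | set(tab["gene_b"])

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, (5, 10))
        scaled = values.copy()
        scaled[2] = 7.0 - 3.5 * scaled[2]
        a = correlation_table(values, list("abcde"))
        b = correlation_table(scaled, list("abcde"))
        np.testing.assert_allclose(np.abs(a["r"]), np.abs(b["r"]), atol=1e-12)
        np.testing.assert_allclose(a["q_value"], b["q_value"], atol=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            correlation_table(np.ones((2, 2)), ["a", "b"])


class TestBhFdr:
    def test_hand_arithmetic(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.04])),
                                   [0.03, 0.03, 0.04])

    def test_single_p(self):
        assert bh_fdr(np.array([0.3]))[0] == pytest.approx(0.3)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_q_at_least_p(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)

    def test_against_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(11)
        p = rng.random(200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_sm, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([1.5]))


class TestKcore:
    def net(self, g):
        return Network(graph=g, kind="test")

    def test_triangle(self):
        cores, hubs = kcore_decompose(self.net(nx.complete_graph(3)))
        assert set(cores.values()) == {2}
        assert hubs == {0, 1, 2}

    def test_path_of_three(self):
        cores, _ = kcore_decompose(self.net(nx.path_graph(3)))
        assert set(cores.values()) == {1}

    def test_k4_plus_pendant(self):
        g = nx.complete_graph(4)
        g.add_edge(3, "pendant")
        cores, hubs = kcore_decompose(self.net(g))
        assert cores["pendant"] == 1
        assert all(cores[i] == 3 for i in range(4))
        assert hubs == {0, 1, 2, 3}

    def test_matches_bruteforce_and_networkx(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(2, 31))
            p = rng.uniform(0.05, 0.5)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            cores, _ = kcore_decompose(self.net(g))
            assert cores == brute_force_cores(g)
            assert cores == nx.core_number(g)

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(23)
        g = nx.gnp_random_graph(15, 0.2, seed=4)
        before, _ = kcore_decompose(self.net(g))
        candidates = [(u, v) for u in g for v in g
                      if u < v and not g.has_edge(u, v)]
        u, v = candidates[int(rng.integers(len(candidates)))]
        g.add_edge(u, v)
        after, _ = kcore_decompose(self.net(g))
        assert all(after[n] >= before[n] for n in before)

    def test_empty_graph(self):
        cores, hubs = kcore_decompose(self.net(nx.Graph()))
        assert cores == {} and hubs == set()


def test_sif_export(tmp_path):
    net = gene_act_network({"a": "up", "b": "down"},
                           rel([("a", "b", "inhibition")]))
    net.write_sif(tmp_path / "n.sif")
    assert (tmp_path / "n.sif").read_text() == "a\tinhibition\tb\n"
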