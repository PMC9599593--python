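"""Weighted key-driver analysis, consolidation, and KD subnetworks."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from painnets import TissueNetwork, annotate_subnetwork, consolidate_kds, \
    kd_subnetwork, pain_gene_overlap, wkda


def random_network(seed=0, n=200, tissue="t0"):
    rng = np.random.default_rng(seed)
    g = nx.erdos_renyi_graph(n, 0.04, seed=int(rng.integers(2**31)))
    for u, v in g.edges:
        g.edges[u, v]["weight"] = float(rng.uniform(0.2, 1.0))
    return TissueNetwork(tissue=tissue,
                         graph=nx.relabel_nodes(g, lambda i: f"g{i}"))


class TestWkda:
    def test_embedded_star_hub_is_significant(self):
        net = random_network(seed=1)
        g = net.graph.copy()
        members = {f"g{i}" for i in range(10)}
        hub = "hub"
        for m in members:
            g.add_edge(hub, m, weight=1.0)
        net = TissueNetwork(tissue="t0", graph=g)
        res = wkda(net, members, n_perm=2_000, seed=2)
        row = res[res["gene"] == hub]
        assert len(row) == 1
        assert row["fdr"].iloc[0] < 0.05

    def test_disjoint_member_set_not_enriched(self):
        net = random_network(seed=3)
        res = wkda(net, {"zzz", "g0"}, n_perm=500, seed=4)
        hubs_without_members = res[res["n_member_neighbors"] == 0]
        assert (hubs_without_members["W"] == 0).all()
        assert (hubs_without_members["pvalue"] >= 0.5).all()

    def test_low_degree_nodes_never_tested(self):
        g = nx.star_graph(6)  # center degree 6, leaves degree 1
        for u, v in g.edges:
            g.edges[u, v]["weight"] = 0.5
        net = TissueNetwork(tissue="t0", graph=nx.relabel_nodes(g, str))
        res = wkda(net, {"1", "2"}, min_degree=5, n_perm=200, seed=5)
        assert set(res["gene"]) == {"0"}

    def test_empty_network_rejected(self):
        net = TissueNetwork(tissue="t0", graph=nx.Graph())
        with pytest.raises(ValueError, match="empty"):
            wkda(net, {"a"})

    def test_self_loops_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "a", weight=0.5)
        with pytest.raises(ValueError, match="self-loops"):
            TissueNetwork(tissue="t0", graph=g)

    def test_bonferroni_mode_is_more_conservative(self):
        net = random_network(seed=6)
        members = {f"g{i}" for i in range(30)}
        fdr = wkda(net, members, n_perm=500, seed=7)
        bonf = wkda(net, members, n_perm=500, seed=7, bonferroni=True)
        merged = fdr.merge(bonf, on="gene", suffixes=("_fdr", "_bonf"))
        assert (merged["fdr_bonf"] >= merged["fdr_fdr"] - 1e-12).all()

    def test_planted_hub_top_ranked(self, default_config, network_draw):
        nets, truth = network_draw
        designated = truth.module_genes(default_config.signal_module_ids[0])
        for tissue, net in nets.items():
            res = wkda(net, designated & set(net.graph.nodes),
                       n_perm=1_000, seed=8)
            assert res["gene"].iloc[0] == truth.hubs[tissue]


class TestConsolidateKds:
    @staticmethod
    def records(entries):
        return pd.DataFrame(
            [(g, t, sig) for g, t, sig in entries],
            columns=["gene", "tissue", "significant"])

    def test_two_tissue_floor_case_is_conservative(self):
        np_rec = self.records([("KCNQ5", "amygdala", True),
                               ("KCNQ5", "caudate putamen", True)])
        ip_rec = self.records([("KCNQ5", "amygdala", True),
                               ("KCNQ5", "caudate putamen", True)])
        out = consolidate_kds(np_rec, ip_rec)
        assert out.iloc[0]["ntissue"] == 2
        assert bool(out.iloc[0]["conservative"])

    def test_single_tissue_not_conservative(self):
        rec = self.records([("G1", "t0", True)])
        out = consolidate_kds(rec, rec)
        assert not bool(out.iloc[0]["conservative"])

    def test_tissue_counts_require_both_conditions(self):
        np_rec = self.records([("G1", "t0", True), ("G1", "t1", True)])
        ip_rec = self.records([("G1", "t0", True), ("G1", "t1", False)])
        out = consolidate_kds(np_rec, ip_rec)
        assert out.iloc[0]["ntissue"] == 1

    def test_ranking_by_tissue_count(self):
        nine = [("SERPINE1", f"t{i}", True) for i in range(9)]
        eight = [("IL1B", f"t{i}", True) for i in range(8)]
        np_rec = self.records(nine + eight)
        out = consolidate_kds(np_rec, np_rec.copy())
        assert list(out["gene"]) == ["SERPINE1", "IL1B"]
        assert list(out["ntissue"]) == [9, 8]

    def test_input_order_invariant(self):
        rec = self.records([("G1", "t0", True), ("G2", "t1", True),
                            ("G1", "t1", True)])
        shuffled = rec.iloc[::-1].reset_index(drop=True)
        pd.testing.assert_frame_equal(consolidate_kds(rec, rec),
                                      consolidate_kds(shuffled, shuffled))


class TestPainGeneOverlap:
    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(100)}
        r = pain_gene_overlap({"g1"}, {"g50"}, universe, n_perm=300, seed=1)
        assert r.pvalue == pytest.approx(1.0)

    def test_identical_small_sets_hit_resolution_floor(self):
        universe = {f"g{i}" for i in range(30)}
        kds = {f"g{i}" for i in range(5)}
        r = pain_gene_overlap(kds, kds, universe, n_perm=2_000, seed=2)
        assert r.pvalue < 0.01

    def test_agrees_with_binomial_tail_at_published_scale(self):
        # 24 key drivers, 94 known genes, universe 22,188, overlap 2:
        # per-draw hit rate 94/22188, so P(X >= 2) for X ~ Bin(24, rate)
        n_perm = 20_000
        r = pain_gene_overlap({f"kd{i}" for i in range(22)} | {"p0", "p1"},
                              {f"p{i}" for i in range(94)},
                              {f"kd{i}" for i in range(22)}
                              | {f"p{i}" for i in range(94)}
                              | {f"bg{i}" for i in range(22_188 - 116)},
                              n_perm=n_perm, seed=3)
        oracle = stats.binom.sf(1, 24, 94 / 22_188)
        se = np.sqrt(oracle * (1 - oracle) / n_perm)
        assert abs(r.pvalue - oracle) < 3 * se + 2 / n_perm


class TestKdSubnetwork:
    @staticmethod
    def net():
        g = nx.Graph()
        g.add_edge("KD1", "N1", weight=0.9)
        g.add_edge("KD1", "N2", weight=0.8)
        g.add_edge("KD2", "N3", weight=0.7)
        g.add_edge("N1", "N4", weight=0.6)  # N4 not adjacent to a KD
        return g

    def test_threshold_boundary(self):
        minp = {"NP": {"N1": 4e-8, "N2": 6e-8}, "IP": {}}
        sub = kd_subnetwork({"KD1"}, self.net(), minp)
        assert "N1" in sub.graph and "N2" not in sub.graph
        assert sub.n_hits_per_condition == {"NP": 1, "IP": 0}

    def test_kd_without_qualifying_neighbor_is_isolated(self):
        sub = kd_subnetwork({"KD2"}, self.net(), {"NP": {}, "IP": {}})
        assert set(sub.graph.nodes) == {"KD2"}
        assert sub.graph.degree("KD2") == 0

    def test_every_node_is_kd_or_adjacent_hit(self):
        minp = {"NP": {"N1": 1e-9, "N3": 1e-9, "N4": 1e-9}, "IP": {}}
        sub = kd_subnetwork({"KD1", "KD2"}, self.net(), minp)
        assert "N4" not in sub.graph  # significant but not KD-adjacent
        for node in sub.graph.nodes:
            assert node in sub.kd_nodes or \
                any(n in sub.kd_nodes for n in self.net().neighbors(node))

    def test_node_set_shrinks_with_stricter_threshold(self):
        minp = {"NP": {"N1": 1e-8, "N2": 1e-10}, "IP": {}}
        loose = kd_subnetwork({"KD1"}, self.net(), minp, gw_threshold=5e-8)
        strict = kd_subnetwork({"KD1"}, self.net(), minp, gw_threshold=1e-9)
        assert set(strict.graph.nodes) <= set(loose.graph.nodes)


class TestAnnotateSubnetwork:
    def test_subnetwork_equal_pathway_fold(self):
        universe = {f"g{i}" for i in range(100)}
        nodes = {f"g{i}" for i in range(10)}
        g = nx.Graph()
        g.add_nodes_from(nodes)
        sub = kd_subnetwork(nodes, g, {"NP": {}, "IP": {}})
        out = annotate_subnetwork(sub, {"p": set(nodes)}, universe)
        assert out[0].fold == pytest.approx(len(universe) / len(nodes))

    def test_zero_overlap_not_significant(self):
        universe = {f"g{i}" for i in range(100)}
        g = nx.Graph()
        g.add_nodes_from({"g0", "g1"})
        sub = kd_subnetwork({"g0", "g1"}, g, {"NP": {}, "IP": {}})
        out = annotate_subnetwork(sub, {"p": {"g50", "g51"}}, universe)
        assert out[0].fold == 0.0
        assert not out[0].significant

    def test_false_positive_rate_controlled(self):
        rng = np.random.default_rng(9)
        universe = {f"g{i}" for i in range(500)}
        pool = sorted(universe)
        n_sig = 0
        for _ in range(100):
            nodes = set(rng.choice(pool, 50, replace=False))
            paths = {f"p{j}": set(rng.choice(pool, 40, replace=False))
                     for j in range(5)}
            g = nx.Graph()
            g.add_nodes_from(nodes)
            sub = kd_subnetwork(nodes, g, {"NP": {}, "IP": {}})
            n_sig += sum(a.significant
                         for a in annotate_subnetwork(sub, paths, universe))
        assert n_sig / (100 * 5) <= 0.05
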