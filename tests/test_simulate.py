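"""The synthetic generator must plant recoverable structure deterministically."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from painnets import SynthConfig, GroundTruth, ld_prune
from painnets import io, simulate


class TestConfigValidation:
    def test_module_sizes_exceeding_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            SynthConfig(n_genes=100, module_sizes=(60, 60))

    @pytest.mark.parametrize("kwargs", [
        {"ld_rho": 1.0}, {"ld_rho": -0.1}, {"signal_shift": -1.0},
        {"n_tissues": 0}, {"planted_hub_fraction_in_set": 1.5},
        {"signal_module_ids": (9,)},
    ])
    def test_out_of_range_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)

    def test_network_too_small_rejected(self):
        with pytest.raises(ValueError, match="network_size"):
            simulate.generate_networks(SynthConfig(network_size=5))


class TestExpression:
    def test_seed_determinism(self, small_config):
        a, _ = simulate.generate_expression(small_config)
        b, _ = simulate.generate_expression(small_config)
        for tissue in a:
            assert a[tissue].to_csv() == b[tissue].to_csv()

    def test_noiseless_single_module_perfectly_correlated(self):
        cfg = SynthConfig(seed=3, n_genes=30, module_sizes=(20,),
                          signal_module_ids=(0,), noise_sd=0.0,
                          n_tissues=1, n_samples_per_tissue=40)
        expr, truth = simulate.generate_expression(cfg)
        mat = expr["tissue0"]
        members = sorted(truth.module_genes(0))
        cor = np.corrcoef(mat.loc[members].to_numpy())
        assert np.allclose(cor, 1.0)

    def test_within_module_correlation_exceeds_between(self, expression_draw):
        expr, truth = expression_draw
        mat = expr["tissue0"]
        lab = np.array([truth.module_assignment.get(g, -1) for g in mat.index])
        cor = np.abs(np.corrcoef(mat.to_numpy()))
        off = ~np.eye(len(lab), dtype=bool)
        same = (lab[:, None] == lab[None, :]) & (lab[:, None] >= 0)
        assert cor[same & off].mean() > cor[~same & off].mean()


class TestGwas:
    def test_seed_determinism(self, small_config):
        t1, _, _ = simulate.generate_gwas(small_config, "IP")
        t2, _, _ = simulate.generate_gwas(small_config, "IP")
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.df, b.df)

    def test_null_pvalues_uniform(self):
        cfg = SynthConfig(seed=5, signal_shift=0.0)
        tables, _, _ = simulate.generate_gwas(cfg, "NP")
        ks = stats.kstest(tables[0].df["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_zero_ld_makes_pruning_a_noop(self):
        cfg = SynthConfig(seed=5, ld_rho=0.0)
        tables, ld, _ = simulate.generate_gwas(cfg, "NP")
        assert len(ld) == 0
        pruned = ld_prune(tables[0], ld)
        assert len(pruned) == len(tables[0])

    def test_marker_fields_in_range(self, gwas_draw):
        tables, _, _ = gwas_draw
        df = tables[0].df
        assert ((df["maf"] > 0) & (df["maf"] <= 0.5)).all()
        assert ((df["info"] >= 0) & (df["info"] <= 1)).all()
        assert (df["pvalue"] > 0).all()
        assert df.groupby("chrom")["pos"].apply(
            lambda s: s.is_monotonic_increasing).all()

    def test_ld_decay_follows_block_structure(self, default_config, gwas_draw):
        _, ld, _ = gwas_draw
        ld_df, _ = simulate.ld_tables(default_config)
        assert np.isclose(ld_df["r2"].max(), default_config.ld_rho)
        # AR(1)-like decay: every emitted value is an integer power of rho
        powers = np.log(ld_df["r2"]) / np.log(default_config.ld_rho)
        assert np.allclose(powers, np.round(powers))


class TestEqtlAndAnnotation:
    def test_every_eqtl_gene_annotated(self, annotation_draw):
        ann, eqtl, _ = annotation_draw
        assert set(eqtl["gene"]) <= set(ann["gene"])

    def test_qvalue_range_gives_filter_work(self, annotation_draw):
        _, eqtl, _ = annotation_draw
        frac_kept = (eqtl["qval"] <= 0.05).mean()
        assert 0.3 < frac_kept < 0.7

    def test_regulome_scores_integer_1_to_7(self, annotation_draw):
        _, _, regulome = annotation_draw
        assert regulome["score"].between(1, 7).all()

    def test_zero_decoys_gives_exact_truth_map(self):
        cfg = SynthConfig(seed=9, eqtl_decoy_fraction=0.0)
        _, eqtl, _ = simulate.generate_gene_annotation_and_eqtl(cfg)
        truth = simulate.base_truth(cfg)
        assert set(zip(eqtl["variant"], eqtl["gene"])) == \
            set(truth.marker_gene.items())


class TestNetworks:
    def test_degree_distribution_heavy_tailed(self, network_draw):
        nets, _ = network_draw
        for net in nets.values():
            degrees = np.array([d for _, d in net.graph.degree])
            assert degrees.max() > 3 * np.median(degrees)

    def test_planted_hub_neighbors_in_designated_set(self, default_config,
                                                     network_draw):
        nets, truth = network_draw
        designated = truth.module_genes(default_config.signal_module_ids[0])
        for tissue, net in nets.items():
            hub = truth.hubs[tissue]
            neigh = set(net.graph.neighbors(hub))
            frac = len(neigh & designated) / len(neigh)
            assert frac >= default_config.planted_hub_fraction_in_set

    def test_same_hub_gene_planted_in_every_tissue(self, network_draw):
        _, truth = network_draw
        assert len(set(truth.hubs.values())) == 1

    def test_no_self_loops_and_valid_weights(self, network_draw):
        nets, _ = network_draw
        for net in nets.values():
            assert all(u != v for u, v in net.graph.edges)
            weights = [w for _, _, w in net.graph.edges(data="weight")]
            assert all(0 < w <= 1 for w in weights)


class TestGeneSets:
    def test_gmt_round_trip(self, tmp_path, small_config):
        pathways, _, _ = simulate.generate_gene_sets(small_config)
        io.write_gmt(pathways, tmp_path / "p.gmt")
        assert io.read_gmt(tmp_path / "p.gmt") == pathways

    def test_planted_pathway_covers_half_its_module(self, small_config):
        pathways, _, truth = simulate.generate_gene_sets(small_config)
        for m in range(len(small_config.module_sizes)):
            module = truth.module_genes(m)
            overlap = len(pathways[f"PW_module{m}"] & module)
            assert overlap >= 0.5 * len(module)

    def test_seed_determinism(self, small_config):
        a = simulate.generate_gene_sets(small_config)
        b = simulate.generate_gene_sets(small_config)
        assert a[0] == b[0] and a[1] == b[1]


class TestMouseExpression:
    def test_seed_determinism(self, small_config):
        a = simulate.generate_mouse_expression(small_config)
        b = simulate.generate_mouse_expression(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_table_covers_full_grid(self, small_config):
        tbl = simulate.generate_mouse_expression(small_config,
                                                 genes=["G0000", "G0001"])
        assert len(tbl) == 3 * 4 * 2
        assert not tbl.duplicated(["model", "tissue", "gene"]).any()
        assert (tbl["expression"] >= 0).all()


class TestRoundTrip:
    def test_all_outputs_parse_with_package_readers(self, tmp_path, small_config):
        from painnets.gwas import read_summary_stats, LDPanel
        truth = simulate.write_all(small_config, tmp_path)
        for tissue in small_config.tissues:
            expr = io.read_expression(tmp_path / f"expression_{tissue}.tsv")
            assert expr.shape == (small_config.n_genes,
                                  small_config.n_samples_per_tissue)
            net = io.read_edge_list(tmp_path / f"network_{tissue}.tsv")
            assert len(net) > 0
        table = read_summary_stats(tmp_path / "gwas_NP_study0.tsv")
        assert len(table) > 0
        assert len(LDPanel.from_tsv(tmp_path / "ld.tsv")) > 0
        io.read_gene_annotation(tmp_path / "genes.tsv")
        io.read_eqtl(tmp_path / "eqtl.tsv")
        io.read_regulome(tmp_path / "regulome.tsv")
        io.read_gmt(tmp_path / "pathways.gmt")
        io.read_gene_list(tmp_path / "pain_genes.txt")
        io.read_mouse_expression(tmp_path / "mouse_expression.tsv")
        restored = GroundTruth.from_json(tmp_path / "truth.json")
        assert restored == truth
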