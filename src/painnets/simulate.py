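"""Synthetic study generator with planted, recoverable structure.

Every pipeline input is emulated at desk scale with known ground truth:

* expression matrices per tissue from a latent-factor model — genes of a
  planted module share one factor (x_g = lambda_g * f + eps, positive
  loadings), unassigned genes are pure noise;
* GWAS summary statistics per study — marker z-scores are N(0, 1) for null
  genes and N(signal_shift, 1) for genes in signal modules (the -log10 p
  inflation is planted on z so the null stays exactly calibrated), two-sided
  p from z; MAF and imputation quality are drawn wide enough that the QC
  filters have work to do; pairwise LD r² decays AR(1)-like within blocks
  of consecutive markers;
* eQTL tables emitting every true marker-gene link (qval ~ U(0, 0.1), so a
  q <= 0.05 filter removes about half) plus decoys, with gene coordinates
  consistent for proximity mapping and regulome-style scores per marker;
* scale-free interaction networks (preferential attachment) with one
  planted hub per tissue rewired toward a designated gene set;
* pathway collections with one high-overlap pathway per planted module, and
  a mouse-model expression table with configurable planted fold changes.

Each generator draws from its own named random stream derived from the
single config seed, so adding one generator never perturbs another, and the
same config is guaranteed to reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
import zlib
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from . import io
from .config import MOUSE_MODELS, MOUSE_TISSUES, SynthConfig, GroundTruth
from .gwas import LDPanel, MarkerTable, write_summary_stats
from .kda import TissueNetwork

GENES_PER_CHROM = 100
GENE_LENGTH = 10_000
GENE_SPACING = 100_000
MARKER_WINDOW = 20_000
_BASES = np.array(list("ACGT"))


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    """Independent named stream under the single config seed."""
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


def gene_ids(config: SynthConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(config.n_genes)]


def gene_annotation(config: SynthConfig) -> pd.DataFrame:
    """Deterministic gene coordinates: ``GENES_PER_CHROM`` genes per
    chromosome, evenly spaced, 1-based inclusive intervals."""
    rows = []
    for i, gene in enumerate(gene_ids(config)):
        chrom = f"chr{i // GENES_PER_CHROM + 1}"
        start = 1 + (i % GENES_PER_CHROM) * GENE_SPACING
        rows.append((gene, chrom, start, start + GENE_LENGTH - 1))
    return pd.DataFrame(rows, columns=io.ANNOTATION_COLUMNS)


def base_truth(config: SynthConfig) -> GroundTruth:
    """Module assignment, signal modules, and the marker->gene truth map."""
    genes = gene_ids(config)
    assignment: dict[str, int] = {}
    offset = 0
    for m, size in enumerate(config.module_sizes):
        for g in genes[offset:offset + size]:
            assignment[g] = m
        offset += size
    panel = marker_panel(config)
    return GroundTruth(
        module_assignment=assignment,
        signal_module_ids=list(config.signal_module_ids),
        marker_gene=dict(zip(panel["id"], panel["gene"])),
    )


def marker_panel(config: SynthConfig) -> pd.DataFrame:
    """Shared marker panel: id, chrom, pos, source gene. Marker counts per
    gene are Poisson (minimum 1); positions fall in a window around the
    source gene and are unique."""
    rng = _rng(config, "panel")
    ann = gene_annotation(config)
    counts = np.maximum(1, rng.poisson(config.markers_per_gene, config.n_genes))
    rows = []
    idx = 0
    for (gene, chrom, start, end), k in zip(ann.itertuples(index=False), counts):
        lo, hi = max(1, start - MARKER_WINDOW), end + MARKER_WINDOW
        positions = np.sort(rng.choice(hi - lo + 1, size=k, replace=False) + lo)
        for pos in positions:
            rows.append((f"rs{idx}", chrom, int(pos), gene))
            idx += 1
    panel = pd.DataFrame(rows, columns=["id", "chrom", "pos", "gene"])
    return panel.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def generate_expression(config: SynthConfig
                        ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Per-tissue expression with planted co-expression modules."""
    truth = base_truth(config)
    genes = gene_ids(config)
    module_of = np.array([truth.module_assignment.get(g, -1) for g in genes])
    out: dict[str, pd.DataFrame] = {}
    for tissue in config.tissues:
        rng = _rng(config, f"expression-{tissue}")
        n_s = config.n_samples_per_tissue
        factors = rng.normal(0.0, config.module_latent_sd,
                             (len(config.module_sizes), n_s))
        loadings = rng.uniform(0.6, 1.0, config.n_genes)
        x = rng.normal(0.0, config.noise_sd, (config.n_genes, n_s))
        in_module = module_of >= 0
        x[in_module] += loadings[in_module, None] * factors[module_of[in_module]]
        out[tissue] = pd.DataFrame(
            x, index=genes, columns=[f"{tissue}_s{j}" for j in range(n_s)])
    return out, truth


def generate_gwas(config: SynthConfig, condition: str
                  ) -> tuple[list[MarkerTable], LDPanel, GroundTruth]:
    """Summary statistics for every study of one condition, plus the LD
    panel shared by all studies."""
    if condition not in ("NP", "IP"):
        raise ValueError(f"condition must be NP or IP, got {condition!r}")
    truth = base_truth(config)
    panel = marker_panel(config)
    signal_genes = truth.signal_genes
    is_signal = panel["gene"].isin(signal_genes).to_numpy()
    ld_df, ld = ld_tables(config)
    tables = []
    for s in range(config.n_studies_per_condition):
        rng = _rng(config, f"gwas-{condition}-{s}")
        z = rng.normal(0.0, 1.0, len(panel))
        z[is_signal] += config.signal_shift
        pvalue = 2.0 * norm.sf(np.abs(z))
        ref = _BASES[rng.integers(0, 4, len(panel))]
        alt = _BASES[(np.array([list("ACGT").index(b) for b in ref])
                      + rng.integers(1, 4, len(panel))) % 4]
        df = pd.DataFrame({
            "chrom": panel["chrom"], "pos": panel["pos"], "id": panel["id"],
            "ref": ref, "alt": alt,
            "maf": rng.uniform(0.01, 0.5, len(panel)),
            "info": rng.uniform(0.1, 1.0, len(panel)),
            "pvalue": np.clip(pvalue, 1e-300, 1.0),
        })
        tables.append(MarkerTable(study=f"{condition}_study{s}",
                                  condition=condition, df=df))
    return tables, ld, truth


def ld_tables(config: SynthConfig) -> tuple[pd.DataFrame, LDPanel]:
    """Pairwise r² within blocks of consecutive markers per chromosome:
    r²(i, j) = ld_rho ** |i - j| (AR(1)-like decay), zero across blocks."""
    panel = marker_panel(config)
    rows = []
    if config.ld_rho > 0:
        for _, chrom_df in panel.groupby("chrom", sort=False):
            ids = chrom_df["id"].to_list()
            for b0 in range(0, len(ids), config.ld_block_size):
                block = ids[b0:b0 + config.ld_block_size]
                for i in range(len(block)):
                    for j in range(i + 1, len(block)):
                        rows.append((block[i], block[j],
                                     config.ld_rho ** (j - i)))
    df = pd.DataFrame(rows, columns=["id1", "id2", "r2"])
    return df, (LDPanel.from_frame(df) if len(df) else LDPanel())


def generate_gene_annotation_and_eqtl(
        config: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene annotation, eQTL table (truth links + decoys), regulome scores.

    Every true marker->gene link appears once with qval ~ U(0, 0.1); decoy
    links pair markers with random other genes at the configured fraction.
    Regulome scores are uniform integers on 1..7.
    """
    rng = _rng(config, "eqtl")
    panel = marker_panel(config)
    ann = gene_annotation(config)
    tissues = config.tissues
    genes = gene_ids(config)
    qvals = rng.uniform(0.0, 0.1, len(panel))
    tiss = rng.choice(tissues, len(panel))
    eqtl = pd.DataFrame({"variant": panel["id"], "gene": panel["gene"],
                         "tissue": tiss, "qval": qvals})
    n_decoy = int(round(config.eqtl_decoy_fraction * len(panel)))
    if n_decoy:
        d_markers = rng.choice(panel["id"].to_numpy(), n_decoy)
        d_genes = rng.choice(genes, n_decoy)
        truth_gene = dict(zip(panel["id"], panel["gene"]))
        keep = np.array([truth_gene[m] != g for m, g in zip(d_markers, d_genes)])
        decoys = pd.DataFrame({
            "variant": d_markers[keep], "gene": d_genes[keep],
            "tissue": rng.choice(tissues, int(keep.sum())),
            "qval": rng.uniform(0.0, 0.1, int(keep.sum())),
        })
        eqtl = pd.concat([eqtl, decoys], axis=0)
    eqtl = (eqtl.drop_duplicates(subset=["variant", "gene", "tissue"])
            .sort_values(["variant", "gene", "tissue"], kind="mergesort")
            .reset_index(drop=True))
    regulome = pd.DataFrame({"variant": panel["id"],
                             "score": rng.integers(1, 8, len(panel))})
    return ann, eqtl, regulome


def generate_networks(config: SynthConfig, designated: set[str] | None = None
                      ) -> tuple[dict[str, TissueNetwork], GroundTruth]:
    """Scale-free tissue networks with one planted hub per tissue.

    The planted hub is rewired so that at least
    ``planted_hub_fraction_in_set`` of its neighbors belong to the
    designated gene set (default: the genes of the first planted signal
    module, the set the downstream key-driver test will probe).
    """
    if config.network_size < 10:
        raise ValueError("network_size must be at least 10")
    truth = base_truth(config)
    if designated is None:
        designated = truth.module_genes(config.signal_module_ids[0])
    else:
        designated = set(designated)
    genes = gene_ids(config)
    # one hub gene planted in every tissue, so cross-tissue consolidation
    # has a recoverable conservative key driver
    hub_rng = _rng(config, "network-hub")
    hub = str(hub_rng.choice(sorted(set(genes) - designated)))
    networks: dict[str, TissueNetwork] = {}
    for tissue in config.tissues:
        rng = _rng(config, f"network-{tissue}")
        members = sorted(designated)
        others = [g for g in genes if g not in designated and g != hub]
        n_fill = config.network_size - len(members) - 1
        if n_fill < 0:
            raise ValueError("network_size smaller than the designated set")
        node_genes = members + [hub] + list(rng.choice(others, n_fill,
                                                       replace=False))
        order = rng.permutation(len(node_genes))
        node_genes = [node_genes[i] for i in order]
        g = nx.barabasi_albert_graph(config.network_size, config.attachment_m,
                                     seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, dict(enumerate(node_genes)))
        in_set = [n for n in node_genes if n in designated]
        # rewire the hub toward the designated set
        deg = max(g.degree(hub), 12)
        need = math.ceil(config.planted_hub_fraction_in_set * deg)
        new_members = list(rng.choice([n for n in in_set if n != hub],
                                      need, replace=False))
        old = [n for n in g.neighbors(hub) if n not in designated]
        keep_old = old[:deg - need]
        g.remove_edges_from([(hub, n) for n in list(g.neighbors(hub))])
        g.add_edges_from((hub, n) for n in new_members + keep_old)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.uniform(0.2, 1.0))
        networks[tissue] = TissueNetwork(tissue=tissue, graph=g)
        truth.hubs[tissue] = hub
    return networks, truth


def generate_gene_sets(config: SynthConfig,
                       pain_gene_seed_set: set[str] | None = None
                       ) -> tuple[dict[str, set[str]], set[str], GroundTruth]:
    """Pathway GMT collection and a known-pain-gene list.

    One pathway per planted module carries >= 50% of that module's genes;
    the rest are random draws from the gene universe. ``pain_gene_seed_set``
    (e.g. the planted hubs) is forced into the pain-gene list.
    """
    rng = _rng(config, "gene-sets")
    truth = base_truth(config)
    genes = np.array(gene_ids(config))
    pathways: dict[str, set[str]] = {}
    for m in range(len(config.module_sizes)):
        members = sorted(truth.module_genes(m))
        n_core = max(1, math.ceil(0.8 * len(members)))
        core = list(rng.choice(members, n_core, replace=False))
        filler_pool = [g for g in genes if g not in members]
        n_fill = max(0, config.pathway_size - n_core)
        pathways[f"PW_module{m}"] = set(core) | set(
            rng.choice(filler_pool, n_fill, replace=False))
    for p in range(config.n_pathways):
        pathways[f"PW_rand{p}"] = set(
            rng.choice(genes, config.pathway_size, replace=False))
    pain_genes = set(rng.choice(genes, 20, replace=False))
    if pain_gene_seed_set:
        pain_genes |= set(pain_gene_seed_set)
    truth.pathway_membership = {k: sorted(v) for k, v in pathways.items()}
    return pathways, pain_genes, truth


def generate_mouse_expression(config: SynthConfig,
                              genes=None, fold: float | None = None,
                              noise_sd: float = 0.0) -> pd.DataFrame:
    """Mouse-model expression table over {SNI, CFA, CTR} x tissues x genes.

    The planted fold change multiplies expression of every listed gene in
    the non-blood tissues of both pain models; controls and blood stay at
    the gene's base level, so the enrichment factor recovers the fold
    exactly when pseudocount = 0 and noise_sd = 0.
    """
    rng = _rng(config, "mouse")
    fold = config.mouse_planted_fold if fold is None else fold
    if genes is None:
        truth = base_truth(config)
        genes = sorted(truth.signal_genes)[:10]
    genes = sorted(genes)
    base = dict(zip(genes, rng.uniform(5.0, 15.0, len(genes))))
    rows = []
    for model in MOUSE_MODELS:
        for tissue in MOUSE_TISSUES:
            for gene in genes:
                value = base[gene]
                if model != "CTR" and tissue != "blood":
                    value *= fold
                if noise_sd > 0:
                    value = max(0.0, value + rng.normal(0.0, noise_sd))
                rows.append((model, tissue, gene, value))
    return pd.DataFrame(rows, columns=["model", "tissue", "gene", "expression"])


def write_all(config: SynthConfig, outdir: str | Path) -> GroundTruth:
    """Generate every input and write it under ``outdir``; returns the
    merged ground truth (also serialized to ``truth.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, truth = generate_expression(config)
    for tissue, mat in expr.items():
        io.write_expression(mat, outdir / f"expression_{tissue}.tsv")
    for condition in ("NP", "IP"):
        tables, _, _ = generate_gwas(config, condition)
        for t in tables:
            write_summary_stats(t, outdir / f"gwas_{t.study}.tsv")
    ld_df, _ = ld_tables(config)
    io.write_tsv(ld_df, outdir / "ld.tsv")
    ann, eqtl, regulome = generate_gene_annotation_and_eqtl(config)
    io.write_tsv(ann, outdir / "genes.tsv")
    io.write_tsv(eqtl, outdir / "eqtl.tsv")
    io.write_tsv(regulome, outdir / "regulome.tsv")
    networks, net_truth = generate_networks(config)
    for tissue, net in networks.items():
        io.write_tsv(net.to_frame(), outdir / f"network_{tissue}.tsv")
    truth.hubs = net_truth.hubs
    pathways, pain_genes, gs_truth = generate_gene_sets(
        config, pain_gene_seed_set=set(net_truth.hubs.values()))
    io.write_gmt(pathways, outdir / "pathways.gmt")
    io.write_gene_list(pain_genes, outdir / "pain_genes.txt")
    truth.pathway_membership = gs_truth.pathway_membership
    mouse = generate_mouse_expression(
        config, genes=sorted(set(net_truth.hubs.values())))
    io.write_tsv(mouse, outdir / "mouse_expression.tsv")
    truth.to_json(outdir / "truth.json")
    return truth
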