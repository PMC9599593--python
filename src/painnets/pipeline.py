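"""End-to-end run of the shared-genetics pipeline on a synthetic study.

The stages mirror the analysis this package implements: per-study GWAS
filtering and LD pruning; marker-to-gene mapping (eQTL + proximity);
per-tissue co-expression module detection; MSEA per study x tissue and
Stouffer meta-analysis per condition; NP/IP module-overlap permutation
test; pathway supernets; weighted key-driver analysis per tissue network
with cross-condition consolidation; pain-gene overlap; KD subnetwork
extraction; and the mouse-model enrichment factor for the conservative key
drivers. Every stage seeds its randomness from the config seed, so a rerun
writes byte-identical tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import simulate, io
from .config import SynthConfig, GroundTruth, CONDITIONS
from .coexpression import (ModuleSet, annotate_gene_sets, annotations_to_frame,
                           compute_tom, detect_modules, select_soft_threshold)
from .enrichfactor import classify_direction, enrich_factor_table
from .gwas import MarkerTable, ld_prune, qc_filter, select_top_fraction
from .kda import (KdSubnetwork, TissueNetwork, consolidate_kds, kd_subnetwork,
                  pain_gene_overlap, wkda)
from .mapping import map_by_eqtl, map_by_proximity, merge_maps
from .msea import build_gene_scores, meta_msea, msea
from .overlap import (OverlapTestResult, build_supernets,
                      condition_pathway_sets, overlap_permutation_test,
                      supernets_to_frame)


def _seed(base: int, tag: str) -> int:
    return (base * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


@dataclass
class PipelineResult:
    config: SynthConfig
    truth: GroundTruth
    module_sets: dict[str, ModuleSet]
    msea_results: pd.DataFrame
    meta_results: dict[str, pd.DataFrame]
    module_overlap: OverlapTestResult
    supernet_frame: pd.DataFrame
    kda_records: dict[str, pd.DataFrame]
    conservative_kds: pd.DataFrame
    pain_overlap: OverlapTestResult | None
    subnetwork: KdSubnetwork
    ef_table: pd.DataFrame
    directions: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in sorted(self.tables.items()):
            io.write_tsv(df, outdir / f"{name}.tsv")


def process_study(table: MarkerTable, ld, maf_min=0.05, info_min=0.3,
                  top_fraction=0.5, r2_max=0.5) -> MarkerTable:
    """QC filter -> top-fraction selection -> iterative LD pruning."""
    return ld_prune(select_top_fraction(qc_filter(table, maf_min, info_min),
                                        top_fraction), ld, r2_max)


def run_pipeline(config: SynthConfig,
                 msea_n_perm: int = 2_000,
                 kda_n_perm: int = 10_000,
                 overlap_n_perm: int = 100_000,
                 gw_threshold: float = 5e-8,
                 fdr_max: float = 0.05) -> PipelineResult:
    seed0 = config.seed
    # --- inputs -----------------------------------------------------------
    expr, truth = simulate.generate_expression(config)
    ann, eqtl, regulome = simulate.generate_gene_annotation_and_eqtl(config)
    networks, net_truth = simulate.generate_networks(config)
    truth.hubs = net_truth.hubs
    pathways, pain_genes, gs_truth = simulate.generate_gene_sets(
        config, pain_gene_seed_set=set(net_truth.hubs.values()))
    truth.pathway_membership = gs_truth.pathway_membership
    gwas_by_condition = {c: simulate.generate_gwas(config, c)
                         for c in CONDITIONS}

    # --- co-expression modules per tissue ---------------------------------
    module_sets: dict[str, ModuleSet] = {}
    module_genes: dict[str, set[str]] = {}
    for tissue, mat in expr.items():
        beta = select_soft_threshold(mat)
        mods = detect_modules(compute_tom(mat, beta), tissue=tissue, beta=beta)
        module_sets[tissue] = mods
        for name, genes in mods.modules.items():
            module_genes[f"{tissue}:{name}"] = set(genes)

    # --- per-study marker processing, mapping, MSEA ------------------------
    msea_rows = []
    min_p: dict[str, dict[str, float]] = {c: {} for c in CONDITIONS}
    for condition in CONDITIONS:
        tables, ld, _ = gwas_by_condition[condition]
        for table in tables:
            pruned = process_study(table, ld)
            mg_map = merge_maps(
                map_by_eqtl(pruned, eqtl),
                map_by_proximity(pruned, ann, regulome))
            scores = build_gene_scores(pruned, mg_map)
            # per-condition minimum mapped GWAS p per gene
            pv = pruned.df.set_index("id")["pvalue"]
            for marker, gene in mg_map[["marker", "gene"]].itertuples(index=False):
                p = float(pv.get(marker, 1.0))
                if p < min_p[condition].get(gene, 1.0):
                    min_p[condition][gene] = p
            for tissue, mods in module_sets.items():
                named = {f"{tissue}:{n}": set(g) for n, g in mods.modules.items()}
                res = msea(named, scores, n_perm=msea_n_perm,
                           seed=_seed(seed0, f"msea-{table.study}-{tissue}"))
                res.insert(0, "tissue", tissue)
                res.insert(0, "study", table.study)
                res.insert(0, "condition", condition)
                msea_rows.append(res)
    msea_results = pd.concat(msea_rows, axis=0).reset_index(drop=True)

    # --- meta-analysis and NP/IP module overlap ----------------------------
    meta_results = {}
    significant: dict[str, set[str]] = {}
    for condition in CONDITIONS:
        sub = msea_results[msea_results["condition"] == condition]
        per_study = [grp[["module", "pvalue"]]
                     for _, grp in sub.groupby("study")]
        meta = meta_msea(per_study, condition=condition, fdr_max=fdr_max)
        meta_results[condition] = meta
        significant[condition] = set(meta.loc[meta["significant"], "module"])
    universe = set(msea_results["module"])
    obs = len(significant["NP"] & significant["IP"])
    module_overlap = overlap_permutation_test(
        len(universe), len(significant["NP"]), len(significant["IP"]),
        obs, n_perm=overlap_n_perm, seed=_seed(seed0, "module-overlap"))

    # --- pathway annotation and supernets ----------------------------------
    ann_frames = []
    for tissue, mods in module_sets.items():
        named = {f"{tissue}:{n}": set(g) for n, g in mods.modules.items()}
        tissue_universe = set(expr[tissue].index)
        ann_frames.append(annotations_to_frame(
            annotate_gene_sets(named, pathways, tissue_universe)))
    annotations = pd.concat(ann_frames, axis=0).reset_index(drop=True)
    cond_sets = {
        c: condition_pathway_sets(
            {m: module_genes[m] for m in significant[c]}, annotations)
        for c in CONDITIONS
    }
    supernets = build_supernets(cond_sets["NP"], cond_sets["IP"])
    supernet_frame = supernets_to_frame(supernets)

    # --- weighted key-driver analysis --------------------------------------
    kda_records: dict[str, pd.DataFrame] = {}
    for condition in CONDITIONS:
        frames = []
        for tissue, net in networks.items():
            for sn in supernets:
                members = set(sn.np_genes if condition == "NP" else sn.ip_genes)
                if not members & set(net.graph.nodes):
                    continue
                frames.append(wkda(
                    net, members, supernet=sn.pathway,
                    n_perm=kda_n_perm,
                    seed=_seed(seed0, f"kda-{condition}-{tissue}-{sn.pathway}")))
        kda_records[condition] = (pd.concat(frames, axis=0).reset_index(drop=True)
                                  if frames else pd.DataFrame())
    if all(len(kda_records[c]) for c in CONDITIONS):
        conservative = consolidate_kds(kda_records["NP"], kda_records["IP"])
    else:
        conservative = pd.DataFrame(
            columns=["gene", "tissues", "ntissue", "conservative"])

    # --- pain-gene overlap and KD subnetwork -------------------------------
    network_universe: set[str] = set()
    consolidated = nx.Graph()
    for net in networks.values():
        network_universe |= set(net.graph.nodes)
        consolidated = nx.compose(consolidated, net.graph)
    kd_genes = set(conservative.loc[conservative["conservative"], "gene"])
    pain_overlap = None
    if kd_genes:
        pain_overlap = pain_gene_overlap(
            kd_genes, pain_genes, network_universe,
            n_perm=overlap_n_perm, seed=_seed(seed0, "pain-overlap"))
    subnetwork = kd_subnetwork(kd_genes, consolidated, min_p,
                               gw_threshold=gw_threshold)

    # --- mouse enrichment factor -------------------------------------------
    mouse = simulate.generate_mouse_expression(
        config, genes=sorted(set(net_truth.hubs.values()) | kd_genes))
    ef = enrich_factor_table(mouse)
    directions = classify_direction(ef)

    tables = {
        "msea": msea_results,
        "meta_np": meta_results["NP"],
        "meta_ip": meta_results["IP"],
        "supernets": supernet_frame,
        "kda_np": kda_records["NP"],
        "kda_ip": kda_records["IP"],
        "conservative_kds": conservative,
        "subnetwork_nodes": subnetwork.node_frame(),
        "subnetwork_edges": subnetwork.edge_frame(),
        "enrich_factor": ef,
        "directions": directions,
    }
    return PipelineResult(
        config=config, truth=truth, module_sets=module_sets,
        msea_results=msea_results, meta_results=meta_results,
        module_overlap=module_overlap, supernet_frame=supernet_frame,
        kda_records=kda_records, conservative_kds=conservative,
        pain_overlap=pain_overlap, subnetwork=subnetwork,
        ef_table=ef, directions=directions, tables=tables)
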