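"""Weighted key-driver analysis (wKDA) on tissue interaction networks.

A key driver is a network hub whose one-edge neighborhood is enriched, by
edge weight, for the genes of a supernet. Candidate hubs are nodes with
enough connections (an absolute degree floor and a degree-distribution
quantile, whichever is larger). The statistic for a hub is

    W = sum of weights of edges from the hub to neighbors in the member set,

tested against a null that permutes the member labels over nodes within
degree-quartile strata — hub degree is the classic confounder of
neighborhood enrichment, and stratifying the label permutation removes it.
One-sided empirical p-values get BH FDR across hubs per (tissue, supernet);
significance at FDR < 0.05 by default.

Key drivers found for both pain conditions in a tissue are consolidated:
Ntissue counts the tissues where a gene is significant in both conditions,
and genes with Ntissue >= 2 are flagged conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import ModuleAnnotation, annotate_gene_sets
from .overlap import OverlapTestResult, overlap_test_sets
from .stats import bh_fdr

KDA_COLUMNS = ["gene", "tissue", "supernet", "degree", "n_member_neighbors",
               "W", "pvalue", "fdr", "significant"]


@dataclass(frozen=True)
class TissueNetwork:
    """Undirected weighted interaction network for one tissue."""

    tissue: str
    graph: nx.Graph = field(repr=False)

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("network contains self-loops")
        for u, v, w in self.graph.edges(data="weight", default=None):
            if w is None or not 0.0 < w <= 1.0:
                raise ValueError(f"edge ({u}, {v}) weight must be in (0, 1]")

    @classmethod
    def from_frame(cls, tissue: str, edges: pd.DataFrame) -> "TissueNetwork":
        g = nx.Graph()
        for u, v, w in edges[["node1", "node2", "weight"]].itertuples(index=False):
            g.add_edge(u, v, weight=float(w))
        return cls(tissue=tissue, graph=g)

    def to_frame(self) -> pd.DataFrame:
        rows = [(u, v, w) for u, v, w in self.graph.edges(data="weight")]
        return pd.DataFrame(rows, columns=["node1", "node2", "weight"])


def _degree_strata(degrees: np.ndarray, n_strata: int = 4) -> np.ndarray:
    qs = np.quantile(degrees, np.linspace(0, 1, n_strata + 1)[1:-1])
    return np.searchsorted(qs, degrees, side="right")


def wkda(net: TissueNetwork, member_genes: set[str], supernet: str = "supernet",
         min_degree: int = 5, hub_quantile: float = 0.75,
         n_perm: int = 10_000, seed: int = 0, fdr_max: float = 0.05,
         bonferroni: bool = False) -> pd.DataFrame:
    """Weighted key-driver analysis of one member set on one tissue network.

    Returns one row per candidate hub. ``bonferroni=True`` switches the
    significance call from BH FDR to Bonferroni-adjusted p (both < 0.05 by
    default); the ``fdr`` column then holds the Bonferroni-adjusted p.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not member_genes & set(g.nodes):
        raise ValueError("member set shares no genes with the network")
    nodes = np.asarray(sorted(g.nodes))
    pos = {n: i for i, n in enumerate(nodes)}
    n = nodes.size
    adj = np.zeros((n, n))
    for u, v, w in g.edges(data="weight"):
        adj[pos[u], pos[v]] = w
        adj[pos[v], pos[u]] = w
    degrees = np.asarray([g.degree(x) for x in nodes], dtype=float)
    threshold = max(min_degree, float(np.quantile(degrees, hub_quantile)))
    hubs = np.flatnonzero(degrees >= threshold)
    if hubs.size == 0:
        import warnings
        warnings.warn("no candidate hubs pass the degree threshold")
        return pd.DataFrame(columns=KDA_COLUMNS)

    member = np.isin(nodes, sorted(member_genes)).astype(float)
    w_obs = adj[hubs] @ member

    rng = np.random.default_rng(seed)
    strata = _degree_strata(degrees)
    perm = np.tile(member, (n_perm, 1))
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        perm[:, idx] = rng.permuted(perm[:, idx], axis=1)
    w_null = adj[hubs] @ perm.T  # (n_hubs, n_perm)
    exceed = (w_null >= w_obs[:, None]).sum(axis=1)
    pvalues = (exceed + 1) / (n_perm + 1)

    out = pd.DataFrame({
        "gene": nodes[hubs],
        "tissue": net.tissue,
        "supernet": supernet,
        "degree": degrees[hubs].astype(int),
        "n_member_neighbors": (adj[hubs] > 0) @ member,
        "W": w_obs,
        "pvalue": pvalues,
    })
    if bonferroni:
        out["fdr"] = np.minimum(1.0, out["pvalue"] * len(out))
    else:
        out["fdr"] = bh_fdr(out["pvalue"])
    out["significant"] = out["fdr"] < fdr_max
    return out.sort_values("fdr", kind="mergesort").reset_index(drop=True)


def consolidate_kds(records_np: pd.DataFrame, records_ip: pd.DataFrame,
                    min_tissues: int = 2) -> pd.DataFrame:
    """Cross-condition consolidation of key drivers.

    A gene counts a tissue when it is significant there for BOTH conditions
    (any supernet). Output is sorted by Ntissue descending then gene id;
    ``conservative`` flags Ntissue >= ``min_tissues``.
    """
    def sig_pairs(records: pd.DataFrame) -> set[tuple[str, str]]:
        hit = records[records["significant"]]
        return set(zip(hit["gene"], hit["tissue"]))

    both = sig_pairs(records_np) & sig_pairs(records_ip)
    per_gene: dict[str, set[str]] = {}
    for gene, tissue in both:
        per_gene.setdefault(gene, set()).add(tissue)
    rows = [(gene, ",".join(sorted(tissues)), len(tissues),
             len(tissues) >= min_tissues)
            for gene, tissues in per_gene.items()]
    out = pd.DataFrame(rows, columns=["gene", "tissues", "ntissue", "conservative"])
    return out.sort_values(["ntissue", "gene"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


def pain_gene_overlap(kd_genes: set[str], known_genes: set[str],
                      universe: set[str], n_perm: int = 100_000,
                      seed: int = 0) -> OverlapTestResult:
    """Permutation overlap of the key drivers with a known-pain-gene list
    over the network gene universe; fold falls back to the permutation mean
    (flagged) when the median overlap is zero."""
    return overlap_test_sets(universe, kd_genes & universe,
                             known_genes & universe, n_perm=n_perm, seed=seed)


@dataclass(frozen=True)
class KdSubnetwork:
    """Key drivers plus their genome-wide-significant one-edge neighbors."""

    graph: nx.Graph = field(repr=False)
    kd_nodes: frozenset[str]
    gwas_hit_nodes: frozenset[str]
    n_hits_per_condition: dict[str, int]

    def node_frame(self) -> pd.DataFrame:
        rows = [(n, "KD" if n in self.kd_nodes else "gwas_hit")
                for n in sorted(self.graph.nodes)]
        return pd.DataFrame(rows, columns=["node", "class"])

    def edge_frame(self) -> pd.DataFrame:
        rows = [(u, v, w) for u, v, w in self.graph.edges(data="weight", default=1.0)]
        return pd.DataFrame(rows, columns=["node1", "node2", "weight"])


def kd_subnetwork(kd_genes: set[str], interaction_net: nx.Graph,
                  gwas_min_p: dict[str, dict[str, float]],
                  gw_threshold: float = 5e-8) -> KdSubnetwork:
    """Extract the KD one-edge subnetwork, keeping only neighbors with a
    genome-wide-significant mapped marker (min p < threshold) in at least
    one condition. KD nodes are always retained, isolated or not.
    """
    kds = kd_genes & set(interaction_net.nodes)
    keep: set[str] = set(kds)
    hits: set[str] = set()
    n_hits = {cond: 0 for cond in gwas_min_p}
    neighbors: set[str] = set()
    for kd in kds:
        neighbors |= set(interaction_net.neighbors(kd))
    for node in sorted(neighbors - kds):
        sig_conditions = [cond for cond, pmap in gwas_min_p.items()
                          if pmap.get(node, 1.0) < gw_threshold]
        if sig_conditions:
            keep.add(node)
            hits.add(node)
            for cond in sig_conditions:
                n_hits[cond] += 1
    sub = interaction_net.subgraph(keep).copy()
    sub.add_nodes_from(kds)  # KDs with no retained neighbor stay as isolates
    return KdSubnetwork(graph=sub, kd_nodes=frozenset(kds),
                        gwas_hit_nodes=frozenset(hits),
                        n_hits_per_condition=n_hits)


def annotate_subnetwork(subnet: KdSubnetwork, pathways: dict[str, set[str]],
                        universe: set[str],
                        alpha: float = 0.05) -> list[ModuleAnnotation]:
    """Fisher/Bonferroni pathway (or GO) enrichment of the subnetwork node
    set; the fold field reports observed/expected overlap."""
    nodes = set(subnet.graph.nodes) & universe
    return annotate_gene_sets({"kd_subnetwork": nodes}, pathways, universe,
                              alpha=alpha)
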