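"""Weighted co-expression module detection and pathway annotation.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta with Pearson
correlation across samples, the soft power beta chosen as the smallest value
whose degree distribution satisfies the scale-free topology criterion.
Topological overlap (TOM) turns shared neighborhoods into a similarity,

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with connectivity k_i = sum_{u != i} a_iu and the sum over u excluding i
and j. Modules are flat clusters of average-linkage hierarchical clustering
on dissimilarity 1 - TOM cut at a fixed height; clusters below the minimum
size are left unassigned. This is a compact deterministic variant of the
WGCNA recipe (static cut rather than dynamic tree cut).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .stats import fisher_enrichment

logger = logging.getLogger(__name__)

FALLBACK_BETA = 6


@dataclass(frozen=True)
class ModuleSet:
    """Named, disjoint gene modules detected in one tissue."""

    tissue: str
    beta: float
    modules: dict[str, frozenset[str]]
    unassigned: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, genes in self.modules.items():
            if seen & genes:
                raise ValueError(f"module {name} overlaps another module")
            seen |= genes

    @property
    def assigned_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.modules.values():
            out |= genes
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.tissue, name, g)
                for name, genes in sorted(self.modules.items())
                for g in sorted(genes)]
        return pd.DataFrame(rows, columns=["tissue", "module", "gene"])


@dataclass(frozen=True)
class ModuleAnnotation:
    """Fisher enrichment of one gene set against one pathway."""

    module: str
    pathway: str
    overlap: int
    fold: float
    pvalue: float
    adjusted_p: float
    significant: bool


def _correlation(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; constant rows correlate 0."""
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info("%d constant gene rows: correlation set to 0", constant.sum())
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd * x.shape[1])
    xn = xc / denom[:, None]
    r = xn @ xn.T * x.shape[1]
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def adjacency(expr: pd.DataFrame, beta: float) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|^beta, unit diagonal."""
    a = np.abs(_correlation(expr.to_numpy(dtype=float))) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """R² of the log10 p(k) vs log10 k regression over degree bins.

    Returns 0 when the slope is positive (not scale-free) or when fewer
    than 3 populated bins exist.
    """
    k = adj.sum(axis=0) - 1.0
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    k_mean, p_k = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size:
            k_mean.append(members.mean())
            p_k.append(members.size / k.size)
    if len(k_mean) < 3:
        return 0.0
    lx, ly = np.log10(k_mean), np.log10(p_k)
    slope, _ = np.polyfit(lx, ly, 1)
    r = np.corrcoef(lx, ly)[0, 1]
    return float(r * r) if slope < 0 else 0.0


def select_soft_threshold(expr: pd.DataFrame, fit_target: float = 0.85,
                          beta_range=range(1, 21),
                          min_mean_connectivity: float = 1.0) -> int:
    """Smallest soft power whose scale-free fit R² reaches ``fit_target``;
    falls back to beta=6 (logged) when none qualifies.

    Powers that leave the network with mean connectivity below
    ``min_mean_connectivity`` are skipped: on pure noise the raw R²
    criterion turns spuriously high once the adjacency is almost empty, so
    a qualifying power must also keep the network connected enough to
    carry modules.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    for beta in beta_range:
        adj = adjacency(expr, beta)
        mean_k = float((adj.sum(axis=0) - 1.0).mean())
        if mean_k < min_mean_connectivity:
            continue
        if scale_free_fit(adj) >= fit_target:
            return int(beta)
    logger.warning("no soft power reached scale-free fit %.2f; using beta=%d",
                   fit_target, FALLBACK_BETA)
    return FALLBACK_BETA


def compute_tom(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Topological overlap matrix of the unsigned adjacency at power beta."""
    a = adjacency(expr, beta)
    return pd.DataFrame(tom_from_adjacency(a), index=expr.index, columns=expr.index)


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=0)
    # shared-neighbor term excludes u in {i, j}: (off @ off) counts u != i, j
    # automatically except u=i or u=j contributions, which are zero on the
    # zero-diagonal matrix.
    num = off @ off + off
    kmin = np.minimum.outer(k, k)
    tom = num / (kmin + 1.0 - off)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(tom: pd.DataFrame, tissue: str = "tissue", beta: float = 0,
                   min_size: int = 10, cut_height: float = 0.9) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM cut at ``cut_height``.

    Clusters smaller than ``min_size`` genes go to the unassigned pool.
    Modules are named M1, M2, ... by decreasing size (ties by gene order).
    """
    genes = np.asarray(tom.index)
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    modules: dict[str, frozenset[str]] = {}
    unassigned: set[str] = set()
    sizes = pd.Series(labels).value_counts()
    rank = 0
    for lab in sizes.index:
        members = frozenset(genes[labels == lab])
        if len(members) >= min_size:
            rank += 1
            modules[f"M{rank}"] = members
        else:
            unassigned |= members
    return ModuleSet(tissue=tissue, beta=beta, modules=modules,
                     unassigned=frozenset(unassigned))


def annotate_gene_sets(gene_sets: dict[str, set[str]],
                       pathways: dict[str, set[str]],
                       universe: set[str],
                       alpha: float = 0.05) -> list[ModuleAnnotation]:
    """One-sided Fisher enrichment of every (gene set, pathway) pair with
    Bonferroni correction across all pairs tested in this call."""
    for name, s in gene_sets.items():
        if not set(s) <= universe:
            raise ValueError(f"gene set {name!r} is not within the universe")
    n_tests = len(gene_sets) * len(pathways)
    out = []
    for mod_name, members in gene_sets.items():
        for pw_name, pw_genes in pathways.items():
            res = fisher_enrichment(set(members), pw_genes & universe, universe)
            adj = min(1.0, res.pvalue * n_tests)
            out.append(ModuleAnnotation(
                module=mod_name, pathway=pw_name, overlap=res.overlap,
                fold=res.fold, pvalue=res.pvalue, adjusted_p=adj,
                significant=adj < alpha,
            ))
    return out


def annotations_to_frame(annotations: list[ModuleAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in annotations])
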