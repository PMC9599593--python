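"""Marker-set enrichment analysis (MSEA) and Stouffer meta-analysis.

MSEA asks whether the GWAS markers mapped to a gene module are shifted
toward stronger association than random gene sets. Each gene carries the
maximum -log10 p over its mapped markers. For a module, a multi-cutoff
chi-square-like statistic compares observed and expected counts of member
genes above a ladder of score quantiles,

    chi = sum_i (O_i - E_i) / sqrt(E_i + kappa),

with the cutoffs at the top 50/25/10/5/1 percent of the scored universe and
the stabilizer kappa = 1. Significance comes from a permutation null of
random gene sets of matched size, stratified by gene marker count (quartile
bins) to offset gene-length bias; the p-value is the one-sided Gaussian
tail of the studentized observed statistic against the permutation moments,
so it can fall below 1/n_perm as the downstream Stouffer combination
requires. BH FDR is applied across modules per study.

Meta-MSEA combines the per-study module p-values within a condition with
the unweighted Stouffer Z (meta-Z = sum Z_i / sqrt(k)), converts back to a
meta-p, and applies BH across modules to give the meta-FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import MarkerTable
from .stats import bh_fdr, stouffer_z, P_FLOOR, P_CEIL

logger = logging.getLogger(__name__)

DEFAULT_TOP_FRACTIONS = (0.5, 0.25, 0.10, 0.05, 0.01)


@dataclass(frozen=True)
class GeneScores:
    """Gene-level association summaries: value = max -log10 p over the
    gene's mapped markers; n_markers supports null stratification."""

    values: pd.Series  # gene id -> max neglog10p
    n_markers: pd.Series  # gene id -> marker count

    def __len__(self) -> int:
        return len(self.values)


def build_gene_scores(markers: MarkerTable, mg_map: pd.DataFrame) -> GeneScores:
    """Summarize each mapped gene by its strongest marker association."""
    per_marker = markers.df.set_index("id")["neglog10p"]
    pairs = mg_map[["marker", "gene"]].drop_duplicates()
    pairs = pairs[pairs["marker"].isin(per_marker.index)]
    scored = pairs.assign(value=per_marker.reindex(pairs["marker"]).to_numpy())
    grouped = scored.groupby("gene")
    return GeneScores(values=grouped["value"].max().sort_index(),
                      n_markers=grouped["marker"].nunique().sort_index())


def msea_statistic(member_values: np.ndarray, all_values: np.ndarray,
                   top_fractions=DEFAULT_TOP_FRACTIONS,
                   kappa: float = 1.0) -> float:
    """Multi-cutoff enrichment statistic for one gene set."""
    member_values = np.asarray(member_values, dtype=float)
    all_values = np.asarray(all_values, dtype=float)
    if member_values.size == 0:
        raise ValueError("member set must be nonempty")
    cutoffs = np.quantile(all_values, [1.0 - f for f in top_fractions])
    frac_above = (all_values[None, :] > cutoffs[:, None]).mean(axis=1)
    o = (member_values[None, :] > cutoffs[:, None]).sum(axis=1)
    e = member_values.size * frac_above
    return float(((o - e) / np.sqrt(e + kappa)).sum())


def _stratified_null(rng: np.random.Generator, values: np.ndarray,
                     strata: np.ndarray, member_mask: np.ndarray,
                     cutoffs: np.ndarray, kappa: float,
                     n_perm: int) -> np.ndarray:
    """Permutation null of the statistic for random same-size gene sets
    drawn within marker-count strata. Vectorized over permutations."""
    n = values.size
    frac_above = (values[None, :] > cutoffs[:, None]).mean(axis=1)
    m = int(member_mask.sum())
    above = values[None, :] > cutoffs[:, None]  # (n_cut, n)
    o_perm = np.zeros((n_perm, cutoffs.size))
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        m_s = int(member_mask[idx].sum())
        if m_s == 0:
            continue
        # pick m_s genes of this stratum per permutation
        keys = rng.random((n_perm, idx.size))
        chosen = idx[np.argpartition(keys, m_s - 1, axis=1)[:, :m_s]]
        for c in range(cutoffs.size):
            o_perm[:, c] += above[c][chosen].sum(axis=1)
    e = m * frac_above
    return ((o_perm - e[None, :]) / np.sqrt(e + kappa)[None, :]).sum(axis=1)


def msea(modules: dict[str, set[str]], scores: GeneScores,
         n_perm: int = 10_000, seed: int = 0,
         top_fractions=DEFAULT_TOP_FRACTIONS, kappa: float = 1.0,
         n_strata: int = 4) -> pd.DataFrame:
    """MSEA of each module against the scored gene universe.

    Returns a frame with one row per testable module: observed statistic,
    permutation-moment p, and BH FDR across modules. Modules without any
    scored gene are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable null")
    rng = np.random.default_rng(seed)
    genes = scores.values.index.to_numpy()
    values = scores.values.to_numpy(dtype=float)
    counts = scores.n_markers.reindex(scores.values.index).to_numpy(dtype=float)
    # marker-count quartile strata (fewer if counts tie heavily)
    qs = np.quantile(counts, np.linspace(0, 1, n_strata + 1)[1:-1])
    strata = np.searchsorted(qs, counts, side="right")
    cutoffs = np.quantile(values, [1.0 - f for f in top_fractions])
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows = []
    for name in sorted(modules):
        members = [gene_pos[g] for g in modules[name] if g in gene_pos]
        if not members:
            logger.warning("module %s has no scored genes; skipped", name)
            continue
        mask = np.zeros(genes.size, dtype=bool)
        mask[members] = True
        chi = msea_statistic(values[mask], values, top_fractions, kappa)
        null = _stratified_null(rng, values, strata, mask, cutoffs, kappa, n_perm)
        sd = null.std(ddof=1)
        z = (chi - null.mean()) / sd if sd > 0 else 0.0
        rows.append((name, mask.sum(), chi, float(z), float(stats.norm.sf(z))))
    out = pd.DataFrame(rows, columns=["module", "n_genes", "chi", "z", "pvalue"])
    if len(out):
        out["fdr"] = bh_fdr(out["pvalue"])
    else:
        out["fdr"] = []
    return out


def meta_msea(per_study: list[pd.DataFrame], condition: str = "",
              fdr_max: float = 0.05) -> pd.DataFrame:
    """Stouffer combination of per-study MSEA p-values per module.

    Each input frame needs columns (module, pvalue). A module is combined
    over the k studies that tested it; modules tested nowhere are absent.
    """
    pooled = pd.concat(
        [df[["module", "pvalue"]] for df in per_study if len(df)], axis=0)
    rows = []
    for module, grp in pooled.groupby("module"):
        p = np.clip(grp["pvalue"].to_numpy(dtype=float), P_FLOOR, P_CEIL)
        meta_z = stouffer_z(p)
        rows.append((condition, module, len(p), meta_z,
                     float(stats.norm.sf(meta_z))))
    out = pd.DataFrame(rows, columns=["condition", "module", "n_studies",
                                      "meta_z", "meta_p"])
    out = out.sort_values("module", kind="mergesort").reset_index(drop=True)
    out["meta_fdr"] = bh_fdr(out["meta_p"])
    out["significant"] = out["meta_fdr"] < fdr_max
    return out
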