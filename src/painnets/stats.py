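"""Shared statistical helpers: BH FDR, Stouffer combination, set enrichment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# clamp p before the normal-quantile transform so Z stays finite
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def stouffer_z(pvalues) -> float:
    """Unweighted Stouffer combination of one-sided p-values into a meta-Z."""
    p = np.clip(np.asarray(pvalues, dtype=float), P_FLOOR, P_CEIL)
    z = stats.norm.isf(p)
    return float(z.sum() / np.sqrt(len(p)))


def stouffer_p(pvalues) -> float:
    """Meta-p from the unweighted Stouffer meta-Z (one-sided)."""
    return float(stats.norm.sf(stouffer_z(pvalues)))


@dataclass(frozen=True)
class SetEnrichment:
    overlap: int
    expected: float
    fold: float
    pvalue: float


def fisher_enrichment(set_a: set, set_b: set, universe: set) -> SetEnrichment:
    """One-sided Fisher exact test for overrepresentation of ``set_b``
    members inside ``set_a`` relative to ``universe``.

    Equivalent to the hypergeometric upper tail P(X >= overlap).
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("tested sets must be subsets of the universe")
    n = len(universe)
    a, b = len(set_a), len(set_b)
    k = len(set_a & set_b)
    table = [[k, a - k], [b - k, n - a - b + k]]
    p = stats.fisher_exact(table, alternative="greater")[1]
    expected = a * b / n if n else 0.0
    fold = k / expected if expected > 0 else 0.0
    return SetEnrichment(overlap=k, expected=expected, fold=fold, pvalue=float(p))
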