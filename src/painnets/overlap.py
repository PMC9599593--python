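"""Permutation test for list overlap and pathway-level supernet assembly.

The overlap test resamples BOTH significant lists uniformly without
replacement from the shared universe in every permutation; a success is a
permuted overlap at least as large as the observation. The p-value is
stored as (s + 1) / (n_perm + 1) so it never reaches zero, and is displayed
as "< 1/n_perm" when no success occurred. The enrichment fold divides the
observation by the median permuted overlap, falling back to the mean
(flagged) when the median is zero.

Supernets merge the NP-side and IP-side gene sets of a pathway whose sets
overlap by more than a minimum fraction (default 15%) on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OverlapTestResult:
    universe_size: int
    n_a: int
    n_b: int
    observed: int
    n_perm: int
    successes: int
    pvalue: float  # (s + 1) / (n_perm + 1)
    fold: float
    fold_from_mean: bool  # True when the permutation median was 0

    @property
    def p_display(self) -> str:
        if self.successes == 0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.pvalue:.3g}"


@dataclass(frozen=True)
class Supernet:
    pathway: str
    np_genes: frozenset[str]
    ip_genes: frozenset[str]
    f_np: float
    f_ip: float

    @property
    def merged(self) -> frozenset[str]:
        return self.np_genes | self.ip_genes


def overlap_permutation_test(universe_size: int, n_a: int, n_b: int,
                             observed: int, n_perm: int = 100_000,
                             seed: int = 0,
                             chunk: int = 10_000) -> OverlapTestResult:
    """Monte-Carlo p-value for the overlap of two subsets of a universe.

    Each permutation draws fresh subsets of sizes ``n_a`` and ``n_b``
    uniformly without replacement and records their overlap.
    """
    if n_a > universe_size or n_b > universe_size:
        raise ValueError("set sizes cannot exceed the universe")
    if observed > min(n_a, n_b):
        raise ValueError("observed overlap exceeds the smaller set")
    rng = np.random.default_rng(seed)
    overlaps = np.empty(n_perm, dtype=np.int64)
    # cap the random-key matrix at ~0.3 GB regardless of universe size
    chunk = max(1, min(chunk, 40_000_000 // max(1, universe_size)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # membership of n_a (resp. n_b) smallest random keys = a uniform subset
        keys_a = rng.random((m, universe_size))
        keys_b = rng.random((m, universe_size))
        # ties among continuous keys have probability zero, so "<= k-th
        # smallest key" selects exactly n_a (resp. n_b) elements
        in_a = keys_a <= np.partition(keys_a, n_a - 1, axis=1)[:, n_a - 1:n_a]
        in_b = keys_b <= np.partition(keys_b, n_b - 1, axis=1)[:, n_b - 1:n_b]
        overlaps[done:done + m] = (in_a & in_b).sum(axis=1)
        done += m
    successes = int((overlaps >= observed).sum())
    pvalue = (successes + 1) / (n_perm + 1)
    med = float(np.median(overlaps))
    if med > 0:
        fold, from_mean = observed / med, False
    else:
        mean = float(overlaps.mean())
        fold = observed / mean if mean > 0 else float("inf")
        from_mean = True
    return OverlapTestResult(universe_size, n_a, n_b, observed, n_perm,
                             successes, pvalue, fold, from_mean)


def overlap_test_sets(universe: set, set_a: set, set_b: set,
                      n_perm: int = 100_000, seed: int = 0) -> OverlapTestResult:
    """Overlap test on explicit sets (must be subsets of ``universe``)."""
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("tested sets must be subsets of the universe")
    return overlap_permutation_test(len(universe), len(set_a), len(set_b),
                                    len(set_a & set_b), n_perm=n_perm,
                                    seed=seed)


def condition_pathway_sets(significant_modules: dict[str, set[str]],
                           annotations: pd.DataFrame) -> dict[str, set[str]]:
    """Union of gene members of the significant modules annotated (at the
    significant level) to each pathway, for one condition.

    ``annotations`` needs columns (module, pathway, significant);
    ``significant_modules`` maps module id -> gene set for the modules that
    passed meta-FDR.
    """
    hits = annotations[annotations["significant"]
                       & annotations["module"].isin(significant_modules)]
    out: dict[str, set[str]] = {}
    for pathway, grp in hits.groupby("pathway"):
        genes: set[str] = set()
        for module in grp["module"]:
            genes |= set(significant_modules[module])
        out[pathway] = genes
    return out


def build_supernets(np_sets: dict[str, set[str]],
                    ip_sets: dict[str, set[str]],
                    min_frac: float = 0.15) -> list[Supernet]:
    """Merge per-pathway NP and IP gene sets whose intersection strictly
    exceeds ``min_frac`` of each side's set."""
    supernets = []
    for pathway in sorted(set(np_sets) & set(ip_sets)):
        a, b = set(np_sets[pathway]), set(ip_sets[pathway])
        inter = len(a & b)
        f_np = inter / len(a) if a else 0.0
        f_ip = inter / len(b) if b else 0.0
        if f_np > min_frac and f_ip > min_frac:
            supernets.append(Supernet(pathway, frozenset(a), frozenset(b),
                                      f_np, f_ip))
    return supernets


def supernets_to_frame(supernets: list[Supernet]) -> pd.DataFrame:
    rows = [(s.pathway, g, g in s.np_genes, g in s.ip_genes)
            for s in supernets for g in sorted(s.merged)]
    return pd.DataFrame(rows, columns=["pathway", "gene", "in_np", "in_ip"])
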