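"""Per-study GWAS summary-statistic filtering and iterative LD pruning.

A study enters the pipeline as a :class:`MarkerTable`. Markers are removed
by quality control (MAF and imputation-quality thresholds, both strict),
ranked so only the top fraction of -log10 p survives, and then thinned so
that no two adjacent surviving markers on a chromosome remain in strong LD.
The LD sweep is repeated to a fixpoint: each pass scans consecutive
survivors in position order and, for each adjacent pair with r² above the
threshold, drops the less significant member.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "maf", "info", "pvalue"]


@dataclass(frozen=True)
class MarkerTable:
    """Summary statistics for one study, sorted by (chrom, pos)."""

    study: str
    condition: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "df", _normalize(self.df))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> set[str]:
        return set(self.df["id"])

    def with_df(self, df: pd.DataFrame) -> "MarkerTable":
        return replace(self, df=df)


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if "neglog10p" not in df.columns:
        df = df.assign(neglog10p=-np.log10(df["pvalue"]))
    return df


class LDPanel:
    """Sparse symmetric marker-pair r² lookup; missing pairs count as 0."""

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r² out of [0,1]: {r2}")
        self._r2[self._key(a, b)] = float(r2)

    def get(self, a: str, b: str) -> float:
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LDPanel":
        panel = cls()
        for a, b, r2 in df[["id1", "id2", "r2"]].itertuples(index=False):
            panel.set(a, b, r2)
        return panel

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDPanel":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def read_summary_stats(path: str | Path, study: str = "study",
                       condition: str = "NP") -> MarkerTable:
    """Parse a summary-statistics TSV, rejecting out-of-range rows.

    Rows with missing fields, pvalue outside (0, 1], MAF outside (0, 0.5],
    or info outside [0, 1] are dropped and counted in the log.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: no marker rows")
    n_raw = len(df)
    ok = (
        df[SUMMARY_COLUMNS].notna().all(axis=1)
        & (df["pvalue"] > 0) & (df["pvalue"] <= 1)
        & (df["maf"] > 0) & (df["maf"] <= 0.5)
        & (df["info"] >= 0) & (df["info"] <= 1)
    )
    df = df[ok]
    if n_raw - len(df):
        logger.info("%s: rejected %d/%d malformed rows", path, n_raw - len(df), n_raw)
    dup = df.duplicated(subset=["chrom", "pos", "id"])
    if dup.any():
        logger.info("%s: dropped %d duplicate markers", path, int(dup.sum()))
        df = df[~dup]
    return MarkerTable(study=study, condition=condition, df=df)


def write_summary_stats(table: MarkerTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.df[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def qc_filter(table: MarkerTable, maf_min: float = 0.05,
              info_min: float = 0.3) -> MarkerTable:
    """Keep markers with MAF strictly above ``maf_min`` and imputation
    quality strictly above ``info_min``."""
    df = table.df
    return table.with_df(df[(df["maf"] > maf_min) & (df["info"] > info_min)])


def select_top_fraction(table: MarkerTable, fraction: float = 0.5) -> MarkerTable:
    """Keep the top ``ceil(fraction * n)`` markers by -log10 p.

    Boundary ties are broken by (chrom, pos) ascending so the selection is
    deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(table) == 0:
        raise ValueError("cannot rank an empty marker table")
    n_keep = math.ceil(fraction * len(table))
    ranked = table.df.sort_values(
        ["neglog10p", "chrom", "pos"], ascending=[False, True, True],
        kind="mergesort",
    )
    return table.with_df(ranked.head(n_keep))


def ld_prune(table: MarkerTable, ld: LDPanel, r2_max: float = 0.5) -> MarkerTable:
    """Iteratively thin adjacent markers in strong LD, keeping the more
    significant one.

    Per chromosome, survivors are scanned in position order; each adjacent
    pair with r² > ``r2_max`` loses its larger-p member (tie: the downstream
    marker is dropped). Sweeps repeat until one removes nothing, so in the
    result no adjacent surviving pair exceeds the threshold. Idempotent.
    """
    kept_parts = []
    for _, chrom_df in table.df.groupby("chrom", sort=False):
        ids = list(chrom_df["id"])
        pval = dict(zip(chrom_df["id"], chrom_df["pvalue"]))
        changed = True
        while changed:
            changed = False
            i = 0
            while i + 1 < len(ids):
                a, b = ids[i], ids[i + 1]
                if ld.get(a, b) > r2_max:
                    # drop the weaker signal; tie -> downstream marker
                    ids.pop(i + 1 if pval[b] >= pval[a] else i)
                    changed = True
                else:
                    i += 1
        kept_parts.append(chrom_df[chrom_df["id"].isin(ids)])
    return table.with_df(pd.concat(kept_parts, axis=0))


def filter_studies(manifest: pd.DataFrame, n_min: int = 10_000,
                   cases_min: int = 500) -> pd.DataFrame:
    """Gate studies on cohort size: sample size and case count thresholds
    (strict) applied to a study manifest with columns
    (study, condition, n, n_cases)."""
    for col in ("study", "condition", "n", "n_cases"):
        if col not in manifest.columns:
            raise ValueError(f"study manifest missing column {col!r}")
    return manifest[(manifest["n"] > n_min) & (manifest["n_cases"] > cases_min)]
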