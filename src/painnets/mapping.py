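"""Linking filtered GWAS markers to genes.

Two evidence paths are combined: tissue eQTL associations (kept at
qval ≤ 0.05) and genomic proximity within 50 kb of the gene body backed by
regulatory evidence (an integer score where higher means stronger support,
kept when strictly greater than 4). The merged map is a set of
(marker, gene, evidence, tissue) rows and is the substrate for gene-level
association scores downstream.
"""

from __future__ import annotations

import pandas as pd

from .gwas import MarkerTable

MAP_COLUMNS = ["marker", "gene", "evidence", "tissue"]


def _as_map(df: pd.DataFrame) -> pd.DataFrame:
    df = df[MAP_COLUMNS].drop_duplicates()
    return df.sort_values(MAP_COLUMNS, kind="mergesort").reset_index(drop=True)


def map_by_eqtl(markers: MarkerTable, eqtl: pd.DataFrame,
                qval_max: float = 0.05) -> pd.DataFrame:
    """One map row per eQTL record whose variant is a surviving marker and
    whose qval ≤ ``qval_max`` (inclusive)."""
    ids = markers.marker_ids
    hit = eqtl[(eqtl["qval"] <= qval_max) & eqtl["variant"].isin(ids)]
    out = pd.DataFrame({
        "marker": hit["variant"],
        "gene": hit["gene"],
        "evidence": "eqtl",
        "tissue": hit["tissue"],
    })
    return _as_map(out)


def map_by_proximity(markers: MarkerTable, annotation: pd.DataFrame,
                     regulome: pd.DataFrame, window_bp: int = 50_000,
                     score_min: int = 4) -> pd.DataFrame:
    """Map markers to genes whose body lies within ``window_bp`` (inclusive;
    distance 0 inside the gene), requiring regulatory evidence strictly
    above ``score_min``. Markers without a score are excluded from this path.
    """
    scores = dict(zip(regulome["variant"], regulome["score"]))
    mdf = markers.df[["id", "chrom", "pos"]]
    mdf = mdf[mdf["id"].map(lambda i: scores.get(i, -1) > score_min)]
    rows = []
    for chrom, genes in annotation.groupby("chrom"):
        sub = mdf[mdf["chrom"] == chrom]
        if sub.empty:
            continue
        for gene, start, end in genes[["gene", "start", "end"]].itertuples(index=False):
            near = sub[(sub["pos"] >= start - window_bp) & (sub["pos"] <= end + window_bp)]
            for mid in near["id"]:
                rows.append((mid, gene, "proximity", "NA"))
    return _as_map(pd.DataFrame(rows, columns=MAP_COLUMNS))


def merge_maps(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Set union preserving evidence provenance; a (marker, gene) pair
    supported by both paths keeps one row per evidence label."""
    frames = [x for x in (a, b) if len(x)]
    if not frames:
        return pd.DataFrame(columns=MAP_COLUMNS)
    return _as_map(pd.concat(frames, axis=0))


def validate_map(mg_map: pd.DataFrame, markers: MarkerTable,
                 annotation: pd.DataFrame) -> None:
    """Referential integrity: every marker and gene in the map must exist."""
    bad_m = set(mg_map["marker"]) - markers.marker_ids
    if bad_m:
        raise ValueError(f"map references unknown markers: {sorted(bad_m)[:5]}")
    bad_g = set(mg_map["gene"]) - set(annotation["gene"])
    if bad_g:
        raise ValueError(f"map references unknown genes: {sorted(bad_g)[:5]}")
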