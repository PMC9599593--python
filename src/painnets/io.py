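"""Readers and writers for the plain-text exchange formats used throughout.

Everything is tab-separated text: summary statistics, LD tables, gene
annotation, eQTL maps, regulome scores, expression matrices, weighted edge
lists, mouse expression tables, and GMT gene-set collections.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

EQTL_COLUMNS = ["variant", "gene", "tissue", "qval"]
ANNOTATION_COLUMNS = ["gene", "chrom", "start", "end"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene coordinates, 1-based inclusive intervals."""
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    if (df["end"] < df["start"]).any():
        raise ValueError(f"{path}: gene end < start")
    return df


def read_eqtl(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, EQTL_COLUMNS)
    if df["qval"].isna().any():
        raise ValueError(f"{path}: missing qval")
    return df


def read_regulome(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["variant", "score"])


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression matrix, genes in rows (index), samples in columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True, index_label="gene")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["node1", "node2", "weight"])


def read_mouse_expression(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["model", "tissue", "gene", "expression"])


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line as ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    lines = []
    for name, members in sets.items():
        desc = descriptions.get(name, "na")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    return {g.strip() for g in Path(path).read_text().splitlines() if g.strip()}


def write_gene_list(genes: set[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(sorted(genes)) + "\n")
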