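"""Mouse-model expression enrichment factor for key-driver genes.

For a gene in a pain model (SNI for neuropathic, CFA for inflammatory) and
a tissue, the enrichment factor is the tissue-over-blood expression ratio
in the model divided by the same ratio in controls:

    EF = [E(model, tissue) / E(model, blood)] / [E(CTR, tissue) / E(CTR, blood)]

A pseudocount (default 1.0) is added to every expression value before any
ratio so zero expression never divides. EF > 1 means the gene is more
tissue-enriched in the pain model than in controls; log2 EF is reported
alongside. Direction labels summarize the sign pattern of log2 EF across
tissues and models: up or down in both models, discordant when the models
disagree in sign in some tissue, mixed otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MOUSE_MODELS

PAIN_MODELS = ("SNI", "CFA")  # SNI = neuropathic model, CFA = inflammatory


@dataclass(frozen=True)
class EnrichFactorRecord:
    gene: str
    model: str
    tissue: str
    ef: float
    log2_ef: float


class MissingObservationError(KeyError):
    """A required (model, tissue, gene) expression cell is absent."""


def _lookup(table: pd.DataFrame, model: str, tissue: str, gene: str) -> float:
    hit = table[(table["model"] == model) & (table["tissue"] == tissue)
                & (table["gene"] == gene)]
    if hit.empty:
        raise MissingObservationError(
            f"no expression for (model={model}, tissue={tissue}, gene={gene})")
    return float(hit["expression"].mean())


def enrich_factor(obs: pd.DataFrame, gene: str, model: str, tissue: str,
                  pseudocount: float = 1.0) -> EnrichFactorRecord:
    """Enrichment factor for one gene in one pain model and tissue.

    ``obs`` holds columns (model, tissue, gene, expression); replicate rows
    for a cell are averaged before the pseudocount and ratios.
    """
    if model not in PAIN_MODELS:
        raise ValueError(f"model must be one of {PAIN_MODELS}, got {model!r}")
    e = {
        (m, t): _lookup(obs, m, t, gene) + pseudocount
        for m in (model, "CTR") for t in (tissue, "blood")
    }
    ef = (e[(model, tissue)] / e[(model, "blood")]) / \
         (e[("CTR", tissue)] / e[("CTR", "blood")])
    return EnrichFactorRecord(gene=gene, model=model, tissue=tissue,
                              ef=ef, log2_ef=float(np.log2(ef)))


def enrich_factor_table(obs: pd.DataFrame, genes=None, models=PAIN_MODELS,
                        tissues=None, pseudocount: float = 1.0) -> pd.DataFrame:
    """Enrichment factors for every (gene, model, non-blood tissue) cell."""
    genes = sorted(set(obs["gene"])) if genes is None else sorted(genes)
    tissues = (sorted(set(obs["tissue"]) - {"blood"})
               if tissues is None else sorted(tissues))
    rows = [enrich_factor(obs, g, m, t, pseudocount).__dict__
            for g in genes for m in models for t in tissues]
    return pd.DataFrame(rows, columns=["gene", "model", "tissue", "ef", "log2_ef"])


def classify_direction(ef_table: pd.DataFrame,
                       threshold: float = 0.0) -> pd.DataFrame:
    """Label each gene's cross-model direction pattern.

    up_both / down_both: log2 EF beyond ``threshold`` with one sign in all
    tested tissues of both models; discordant: the two models carry opposite
    (beyond-threshold) signs in some tissue; mixed: anything else, including
    tissues where |log2 EF| <= threshold ("did not change").
    """
    rows = []
    for gene, grp in ef_table.groupby("gene"):
        lfc = grp.set_index(["model", "tissue"])["log2_ef"]
        up = lfc > threshold
        down = lfc < -threshold
        label = "mixed"
        if up.all():
            label = "up_both"
        elif down.all():
            label = "down_both"
        else:
            by_tissue = grp.pivot_table(index="tissue", columns="model",
                                        values="log2_ef")
            if by_tissue.shape[1] == 2:
                a, b = by_tissue.iloc[:, 0], by_tissue.iloc[:, 1]
                opposite = ((a > threshold) & (b < -threshold)) | \
                           ((a < -threshold) & (b > threshold))
                if opposite.any():
                    label = "discordant"
        rows.append((gene, label))
    return pd.DataFrame(rows, columns=["gene", "direction"])
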