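"""Configuration and ground-truth containers for the synthetic study generator.

The generator emulates the statistical structure of the real study inputs
(GWAS summary statistics with block LD, tissue expression with planted
co-expression modules, eQTL maps, scale-free interaction networks with
planted hubs, pathway collections, and mouse-model expression tables) so that
every pipeline stage can be tested against known truth without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

CONDITIONS = ("NP", "IP")
MOUSE_MODELS = ("SNI", "CFA", "CTR")
MOUSE_TISSUES = ("brain", "DRG", "spinal cord", "blood")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults describe the desk-scale study conditions: a few hundred genes
    across a handful of tissues, a handful of GWASs per pain condition, and
    planted structure (co-expression modules, association signal, network
    hubs) strong enough to be recoverable but not trivial.
    """

    seed: int = 0
    # expression
    n_genes: int = 600
    n_samples_per_tissue: int = 120
    n_tissues: int = 3
    module_sizes: tuple[int, ...] = (50, 50, 50, 50, 50, 50)
    module_latent_sd: float = 1.0
    noise_sd: float = 0.4
    # GWAS
    markers_per_gene: float = 3.0
    ld_block_size: int = 10
    ld_rho: float = 0.8
    signal_module_ids: tuple[int, ...] = (0, 1)
    signal_shift: float = 2.0
    n_studies_per_condition: int = 2
    # eQTL / annotation
    eqtl_decoy_fraction: float = 0.3
    # networks
    network_size: int = 300
    attachment_m: int = 3
    planted_hub_fraction_in_set: float = 0.7
    # pathways
    n_pathways: int = 20
    pathway_size: int = 40
    # mouse expression
    mouse_planted_fold: float = 2.0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples_per_tissue": self.n_samples_per_tissue,
            "n_tissues": self.n_tissues,
            "ld_block_size": self.ld_block_size,
            "n_studies_per_condition": self.n_studies_per_condition,
            "network_size": self.network_size,
            "attachment_m": self.attachment_m,
            "n_pathways": self.n_pathways,
            "pathway_size": self.pathway_size,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)} "
                f"> n_genes = {self.n_genes}"
            )
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if self.signal_shift < 0:
            raise ValueError("signal_shift must be >= 0")
        if not 0.0 <= self.planted_hub_fraction_in_set <= 1.0:
            raise ValueError("planted_hub_fraction_in_set must be in [0, 1]")
        if any(m < 0 or m >= len(self.module_sizes) for m in self.signal_module_ids):
            raise ValueError("signal_module_ids must index module_sizes")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{t}" for t in range(self.n_tissues)]


@dataclass
class GroundTruth:
    """Planted structure of one synthetic study, sufficient to score recovery.

    ``module_assignment`` maps gene id -> planted module index (genes outside
    every module are absent); ``hubs`` maps tissue -> planted hub gene;
    ``marker_gene`` maps marker id -> source gene id.
    """

    module_assignment: dict[str, int] = field(default_factory=dict)
    signal_module_ids: list[int] = field(default_factory=list)
    hubs: dict[str, str] = field(default_factory=dict)
    pathway_membership: dict[str, list[str]] = field(default_factory=dict)
    marker_gene: dict[str, str] = field(default_factory=dict)

    @property
    def signal_genes(self) -> set[str]:
        sig = set(self.signal_module_ids)
        return {g for g, m in self.module_assignment.items() if m in sig}

    def module_genes(self, module_id: int) -> set[str]:
        return {g for g, m in self.module_assignment.items() if m == module_id}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            module_assignment={k: int(v) for k, v in raw["module_assignment"].items()},
            signal_module_ids=[int(m) for m in raw["signal_module_ids"]],
            hubs=dict(raw["hubs"]),
            pathway_membership={k: list(v) for k, v in raw["pathway_membership"].items()},
            marker_gene=dict(raw["marker_gene"]),
        )
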