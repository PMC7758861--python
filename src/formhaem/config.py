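"""Pipeline configuration: defaults, validation, normalization.

Every analysis parameter defaults to the documented method constant
(10% mito, 1200 genes, 3 SD, 4.5% doublets, depth 20, VAF 0.3, ...).
Unknown keys and out-of-range values are rejected together, and
normalization is idempotent.
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from formhaem.errors import ConfigurationError

STAGES = ("simulate", "sc-qc", "sc-cluster", "sc-score", "mutsig", "chem")


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class QcBlock(_Block):
    max_mito_fraction: float = Field(0.10, gt=0)
    min_genes: int = Field(1200, gt=0)
    umi_sd_limit: float = Field(3.0, gt=0)
    doublet_removal_fraction: float = Field(0.045, ge=0, lt=1)


class DoubletBlock(_Block):
    simulated_fraction: float = Field(0.25, ge=0)
    n_pcs: int = Field(50, ge=2)
    k_neighbors: int = Field(30, ge=1)


class ClusterBlock(_Block):
    n_pcs: int = Field(50, ge=2)
    k_graph: int = Field(15, ge=1)
    resolution: float = Field(1.0, gt=0)
    subcluster_resolution: float = Field(0.6, gt=0)
    n_hvg: int = Field(2000, ge=10)


class FilterBlock(_Block):
    min_depth: int = Field(20, ge=0)
    min_vaf: float = Field(0.3, ge=0, le=1)
    excluded_filter_flags: list[str] = Field(default_factory=lambda: ["normal_artifact"])
    exclude_multiallelic: bool = True


class ScRnaBlock(_Block):
    n_cells_per_sample: int = Field(2000, gt=0)
    n_genes: int = Field(2000, gt=0)
    doublet_fraction: float = Field(0.05, ge=0, lt=1)
    lowquality_fraction: float = Field(0.05, ge=0, lt=1)
    hsc_fraction: dict[str, float] = Field(default_factory=lambda: {"WT": 0.06})


class MutBlock(_Block):
    n_chromosomes: int = Field(2, ge=1)
    chromosome_length: int = Field(300_000, ge=3)
    gene_density: float = Field(0.4, ge=0, lt=1)
    sbs_mean: dict[str, float] = Field(default_factory=lambda: {"WT": 100.0, "DKO": 300.0})
    dbs_mean: dict[str, float] = Field(default_factory=lambda: {"WT": 0.5, "DKO": 4.0})
    indel_mean: dict[str, float] = Field(default_factory=lambda: {"WT": 20.0, "DKO": 40.0})
    n_genomes_per_genotype: dict[str, int] = Field(
        default_factory=lambda: {"WT": 5, "DKO": 6}
    )
    signature_weights: dict[str, float] = Field(
        default_factory=lambda: {"clocklike-cpg": 0.5, "ta-heavy": 0.3, "flat": 0.2}
    )
    strand_bias_odds: dict[str, float] = Field(default_factory=dict)
    artifact_rate: float = Field(5.0, ge=0)
    signature_csv: str | None = None


class ChemBlock(_Block):
    calib_levels_mg_per_l: list[float] = Field(
        default_factory=lambda: [0.1, 0.2, 0.5, 1.0, 2.0, 5.0]
    )
    n_replicates: int = Field(3, ge=1)
    noise_cv: float = Field(0.10, ge=0)
    group_true_means_uM: dict[str, float] = Field(
        default_factory=lambda: {"WT": 4.0, "Aldh2": 9.0, "Adh5": 11.0, "DKO": 44.0}
    )
    group_n: dict[str, int] = Field(
        default_factory=lambda: {"WT": 43, "Aldh2": 20, "Adh5": 51, "DKO": 4}
    )
    reference_group: str = "WT"
    precision_bound: float = Field(0.15, gt=0)


class PipelineConfig(_Block):
    seed: int = 0
    stages: list[Literal["simulate", "sc-qc", "sc-cluster", "sc-score", "mutsig", "chem"]] = Field(
        default_factory=lambda: list(STAGES)
    )
    genesets: dict[str, str] = Field(default_factory=dict)  # name -> CSV path
    qc: QcBlock = Field(default_factory=QcBlock)
    doublet: DoubletBlock = Field(default_factory=DoubletBlock)
    clustering: ClusterBlock = Field(default_factory=ClusterBlock)
    filter: FilterBlock = Field(default_factory=FilterBlock)
    scrna: ScRnaBlock = Field(default_factory=ScRnaBlock)
    mut: MutBlock = Field(default_factory=MutBlock)
    chem: ChemBlock = Field(default_factory=ChemBlock)


def normalize(raw: dict | None) -> dict:
    """Inject defaults into a raw mapping; idempotent."""
    config = PipelineConfig.model_validate(raw or {})
    return config.model_dump()


def validate_config(path_or_dict: str | dict | None) -> PipelineConfig:
    """Load, validate and default-fill a configuration.

    Raises :class:`ConfigurationError` listing every unknown key, type
    mismatch or out-of-range value together.
    """
    if isinstance(path_or_dict, str):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = path_or_dict
    try:
        return PipelineConfig.model_validate(raw or {})
    except ValidationError as exc:
        messages = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigurationError("; ".join(messages)) from exc
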