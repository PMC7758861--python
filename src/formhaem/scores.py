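"""Per-cell gene-program scores.

* :func:`module_score` — the printed geneset score
  ``score = (1/n) * sum_g ln(x_g + 1)`` with ``x_g`` the total-count
  normalized expression of gene ``g`` and ``n`` the full geneset size
  (genes absent from the matrix contribute 0 but still count in ``n``).
* :func:`cell_cycle_assign` — S and G2/M program scores against
  expression-matched control genes, with G1 as the default phase.
* :func:`dna_repair_deg_summary` — intersection of per-cluster DEG lists
  with a repair geneset: count and median fold-change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

from formhaem.errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """Named gene list; duplicates removed, original order preserved."""

    name: str
    genes: list[str]
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise InputError(f"geneset {self.name!r} is empty")
        self.genes = list(dict.fromkeys(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_csv(cls, path: str, name: str | None = None) -> "GeneSet":
        """Load a two-column CSV (set name, gene); optionally filter by name."""
        table = pd.read_csv(path, header=None, names=["set", "gene"])
        if name is not None:
            table = table[table["set"] == name]
        else:
            name = str(table["set"].iloc[0])
            table = table[table["set"] == name]
        return cls(name=name, genes=table["gene"].astype(str).tolist())


@dataclass
class ModuleScoreResult:
    scores: pd.Series
    geneset: str
    n_genes_used: int
    n_geneset: int


def module_score(adata: ad.AnnData, geneset: GeneSet) -> ModuleScoreResult:
    """Mean ln(x+1) of the geneset's normalized expression per cell."""
    present = [g for g in geneset.genes if g in adata.var_names]
    if not present:
        raise InputError(f"no gene of geneset {geneset.name!r} present in the matrix")
    missing = set(geneset.genes) - set(present)
    if missing:
        logger.info(
            "geneset %s: %d genes absent from matrix contribute 0", geneset.name, len(missing)
        )
    X = adata[:, present].X
    if sp.issparse(X):
        X = np.asarray(X.todense())
    total = np.log1p(np.asarray(X, dtype=float)).sum(axis=1)
    scores = pd.Series(total / len(geneset), index=adata.obs_names, name=geneset.name)
    return ModuleScoreResult(
        scores=scores, geneset=geneset.name, n_genes_used=len(present), n_geneset=len(geneset)
    )


@dataclass
class CellCycleCall:
    s_score: pd.Series
    g2m_score: pd.Series
    phase: pd.Series


def cell_cycle_assign(
    adata: ad.AnnData,
    s_genes: GeneSet,
    g2m_genes: GeneSet,
    seed: int = 0,
    n_bins: int = 25,
    ctrl_size: int = 50,
) -> CellCycleCall:
    """Score S and G2/M programs and call a phase per cell.

    Program score = mean log1p expression of program genes minus the mean
    of control genes drawn (seeded) from expression-matched bins. Phase is
    the argmax of (S, G2M) when that maximum is positive, else G1.
    """
    s_present = [g for g in s_genes.genes if g in adata.var_names]
    g2m_present = [g for g in g2m_genes.genes if g in adata.var_names]
    if not s_present or not g2m_present:
        raise InputError("cell-cycle genesets do not overlap the matrix")
    work = adata.copy()
    sc.pp.log1p(work)
    sc.tl.score_genes(
        work, s_present, score_name="S_score", ctrl_size=ctrl_size, n_bins=n_bins,
        random_state=seed,
    )
    sc.tl.score_genes(
        work, g2m_present, score_name="G2M_score", ctrl_size=ctrl_size, n_bins=n_bins,
        random_state=seed,
    )
    s = work.obs["S_score"]
    g2m = work.obs["G2M_score"]
    phase = pd.Series("G1", index=work.obs_names, name="phase")
    s_wins = (s >= g2m) & (s > 0)
    g2m_wins = (g2m > s) & (g2m > 0)
    phase[s_wins] = "S"
    phase[g2m_wins] = "G2M"
    return CellCycleCall(s_score=s, g2m_score=g2m, phase=phase)


def dna_repair_deg_summary(
    deg_tables: dict[tuple[str, int], pd.DataFrame],
    repair_set: GeneSet,
) -> pd.DataFrame:
    """Count repair-gene DEGs and their median fold-change per (genotype, cluster)."""
    repair = set(repair_set.genes)
    rows = []
    for (genotype, cluster_id), table in deg_tables.items():
        if not {"gene", "log2fc"}.issubset(table.columns):
            raise InputError("DEG tables need 'gene' and 'log2fc' columns")
        hits = table[table["gene"].isin(repair)]
        rows.append(
            dict(
                genotype=genotype,
                cluster=cluster_id,
                n_repair_degs=len(hits),
                median_log2fc=float(hits["log2fc"].median()) if len(hits) else None,
            )
        )
    return pd.DataFrame(rows, columns=["genotype", "cluster", "n_repair_degs", "median_log2fc"])
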