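"""Cell-level quality control: simulated-doublet scoring, threshold
filters, and total-count normalization.

The stage order follows the analysis it reimplements: (1) score every
cell against synthetic doublets and drop the top-scoring fraction per
sample, (2) remove cells with a high mitochondrial UMI fraction, too few
expressed genes, or an outlying total UMI count, (3) normalize survivors
to a common total count. Default thresholds: mito fraction > 10%
(strict), fewer than 1200 expressed genes, totals beyond 3 standard
deviations of the per-sample mean, and removal of the top 4.5% doublet
scores per sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from formhaem.errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    max_mito_fraction: float = 0.10
    min_genes: int = 1200
    umi_sd_limit: float = 3.0
    doublet_removal_fraction: float = 0.045

    def __post_init__(self) -> None:
        if min(self.max_mito_fraction, self.min_genes, self.umi_sd_limit) <= 0:
            raise InputError("QC thresholds must be strictly positive")
        if not 0 <= self.doublet_removal_fraction < 1:
            raise InputError("doublet_removal_fraction must be in [0, 1)")


@dataclass
class DoubletConfig:
    simulated_fraction: float = 0.25
    n_pcs: int = 50
    k_neighbors: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1 or self.n_pcs < 2:
            raise InputError("k_neighbors >= 1 and n_pcs >= 2 required")


@dataclass
class QCReport:
    """Per-cell flags and per-sample retained/removed tallies."""

    per_cell: pd.DataFrame
    per_sample: pd.DataFrame = field(default_factory=pd.DataFrame)

    @staticmethod
    def summarize(per_cell: pd.DataFrame, samples: pd.Series) -> "QCReport":
        flags = per_cell[
            [c for c in per_cell.columns if c.startswith("fail_") or c == "removed_as_doublet"]
        ]
        removed = flags.any(axis=1)
        summary = (
            pd.DataFrame({"sample": samples, "removed": removed})
            .groupby("sample")["removed"]
            .agg(removed="sum", total="count")
            .assign(retained=lambda d: d["total"] - d["removed"])
            .reset_index()
        )
        return QCReport(per_cell=per_cell, per_sample=summary)


def _raw_counts(adata: ad.AnnData) -> sp.csr_matrix:
    counts = adata.layers.get("counts", adata.X)
    return sp.csr_matrix(counts)


def _lognorm_pcs(counts: sp.csr_matrix, n_pcs: int, seed: int) -> np.ndarray:
    totals = np.asarray(counts.sum(axis=1)).ravel()
    target = np.median(totals[totals > 0])
    scale = np.divide(target, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0)
    norm = sp.diags(scale) @ counts
    logged = norm.copy()
    logged.data = np.log1p(logged.data)
    n_comp = min(n_pcs, logged.shape[0] - 1, logged.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    return pca.fit_transform(np.asarray(logged.todense()))


def simulate_and_score_doublets(adata: ad.AnnData, config: DoubletConfig) -> np.ndarray:
    """Score each observed cell by its proximity to synthetic doublets.

    Synthetic doublets are sums of the raw count profiles of uniformly
    sampled distinct cell pairs. The combined observed+synthetic set is
    total-count normalized, log1p transformed and projected to principal
    components; a cell's score is the fraction of its k nearest neighbours
    (Euclidean, excluding itself) that are synthetic.
    """
    n = adata.n_obs
    if n < config.k_neighbors + 1:
        raise InputError(f"need more than k_neighbors={config.k_neighbors} cells, got {n}")
    rng = np.random.default_rng(config.seed)
    counts = _raw_counts(adata)

    n_synth = int(round(config.simulated_fraction * n))
    if n_synth > 0:
        first = rng.integers(0, n, size=n_synth)
        offset = rng.integers(1, n, size=n_synth)
        second = (first + offset) % n  # distinct partner
        synth = counts[first] + counts[second]
        combined = sp.vstack([counts, synth]).tocsr()
    else:
        combined = counts

    pcs = _lognorm_pcs(combined, config.n_pcs, config.seed)
    k = config.k_neighbors
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs[:n])
    neighbors = idx[:, 1:]  # drop self (nearest is the point itself)
    scores = (neighbors >= n).mean(axis=1)
    return scores.astype(float)


def remove_top_doublets(
    adata: ad.AnnData, scores: np.ndarray, thresholds: QcThresholds
) -> tuple[ad.AnnData, QCReport]:
    """Drop the ceil(fraction·n) highest-scoring cells within each sample.

    Ties are broken by descending score then ascending cell identifier, so
    removal counts are reproducible.
    """
    if len(scores) != adata.n_obs:
        raise InputError("one doublet score per cell required")
    samples = adata.obs["sample"].astype(str)
    removed = pd.Series(False, index=adata.obs_names)
    score_s = pd.Series(np.asarray(scores, dtype=float), index=adata.obs_names)
    for sample_name, cells in samples.groupby(samples):
        n_remove = math.ceil(thresholds.doublet_removal_fraction * len(cells))
        if n_remove == 0:
            continue
        ranked = pd.DataFrame(
            {"cell": cells.index, "score": score_s.loc[cells.index].to_numpy()}
        ).sort_values(["score", "cell"], ascending=[False, True])
        removed.loc[ranked["cell"].iloc[:n_remove]] = True
    per_cell = pd.DataFrame(
        {"doublet_score": score_s, "removed_as_doublet": removed}, index=adata.obs_names
    )
    report = QCReport.summarize(per_cell, samples)
    return adata[~removed.values].copy(), report


def qc_filter(
    adata: ad.AnnData, thresholds: QcThresholds
) -> tuple[ad.AnnData, QCReport]:
    """Apply the mito-fraction, gene-count and UMI-outlier rules.

    A cell is removed iff mito fraction > max (strict), expressed genes <
    min (strict), or its total UMI count lies further than
    ``umi_sd_limit`` standard deviations from its sample's mean. The
    mean/SD are computed per sample over the cells given here, i.e. after
    doublet removal when run in stage order.
    """
    if adata.n_obs == 0:
        raise InputError("empty matrix")
    counts = _raw_counts(adata)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    n_genes = counts.getnnz(axis=1)

    if "mito" in adata.var.columns:
        mito_mask = adata.var["mito"].to_numpy(dtype=bool)
    else:
        mito_mask = adata.var_names.str.startswith("mt-").to_numpy()
    if mito_mask.any():
        mito_counts = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
        mito_frac = np.divide(
            mito_counts, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0
        )
        fail_mito = mito_frac > thresholds.max_mito_fraction
    else:
        logger.warning("no mitochondrial genes annotated; mito rule skipped")
        mito_frac = np.zeros(adata.n_obs)
        fail_mito = np.zeros(adata.n_obs, dtype=bool)

    fail_genes = n_genes < thresholds.min_genes

    samples = adata.obs["sample"].astype(str).to_numpy()
    fail_umi = np.zeros(adata.n_obs, dtype=bool)
    for sample_name in np.unique(samples):
        rows = samples == sample_name
        mean, sd = totals[rows].mean(), totals[rows].std(ddof=0)
        if sd > 0:
            fail_umi[rows] = np.abs(totals[rows] - mean) > thresholds.umi_sd_limit * sd

    per_cell = pd.DataFrame(
        {
            "mito_fraction": mito_frac,
            "n_genes": n_genes,
            "total_umi": totals,
            "fail_mito": fail_mito,
            "fail_genes": fail_genes,
            "fail_umi_sd": fail_umi,
        },
        index=adata.obs_names,
    )
    keep = ~(fail_mito | fail_genes | fail_umi)
    report = QCReport.summarize(per_cell, adata.obs["sample"].astype(str))
    return adata[keep].copy(), report


def normalize_total(adata: ad.AnnData, target_sum: float | None = None) -> ad.AnnData:
    """Scale each cell to a common total count; raw counts kept in a layer.

    ``target_sum`` defaults to the median per-cell total. Cells with zero
    total are removed with a warning.
    """
    counts = _raw_counts(adata)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        n_zero = int((totals == 0).sum())
        logger.warning("removing %d zero-total cells before normalization", n_zero)
        adata = adata[totals > 0].copy()
        counts = _raw_counts(adata)
        totals = totals[totals > 0]
    if target_sum is None:
        target_sum = float(np.median(totals))
    if target_sum <= 0:
        raise InputError("target_sum must be > 0")
    out = adata.copy()
    out.layers["counts"] = counts.copy()
    out.X = sp.diags(target_sum / totals) @ counts
    out.uns["normalization_target_sum"] = target_sum
    return out


def run_qc_stage(
    adata: ad.AnnData,
    thresholds: QcThresholds | None = None,
    doublet_config: DoubletConfig | None = None,
) -> tuple[ad.AnnData, QCReport]:
    """Doublet filter, then QC rules, then normalization.

    Returns the clean normalized matrix and a combined report whose
    ``per_cell`` table covers every input cell.
    """
    thresholds = thresholds or QcThresholds()
    doublet_config = doublet_config or DoubletConfig()
    scores = simulate_and_score_doublets(adata, doublet_config)
    after_doublets, doublet_report = remove_top_doublets(adata, scores, thresholds)
    filtered, rule_report = qc_filter(after_doublets, thresholds)
    normalized = normalize_total(filtered)

    per_cell = doublet_report.per_cell.join(rule_report.per_cell, how="left")
    for col in ("fail_mito", "fail_genes", "fail_umi_sd"):
        values = per_cell[col].to_numpy(dtype=object)
        per_cell[col] = np.array([bool(v) if v == v and v is not None else False for v in values])
    report = QCReport.summarize(per_cell, adata.obs["sample"].astype(str))
    return normalized, report
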