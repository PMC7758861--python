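"""Clustering, marker annotation, label transfer, occupancy and scaling.

Unsupervised structure is found by Louvain community detection on a
k-nearest-neighbour graph built in PCA space of log1p-transformed,
highly-variable-gene-restricted expression. Cluster identities are then
assigned automatically from a marker table (the original annotation step
was manual and is replaced here by the argmax of scaled marker scores).
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, field

import anndata as ad
import igraph
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from formhaem.errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_N_HVG = 2000
DEFAULT_RESOLUTION = 1.0
SUBCLUSTER_RESOLUTION = 0.6


@dataclass
class ClusterAssignment:
    """Per-cell cluster ids plus optional per-cluster identity labels."""

    labels: np.ndarray
    params: dict = field(default_factory=dict)
    identities: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def identity_per_cell(self) -> np.ndarray:
        return np.array([self.identities.get(c, "unassigned") for c in self.labels])


@dataclass
class MarkerTable:
    """Population name -> marker gene list."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        if any(len(v) == 0 for v in self.markers.values()):
            raise InputError("marker lists must be non-empty")


def _log1p_hvg_matrix(
    adata: ad.AnnData, n_hvg: int = DEFAULT_N_HVG
) -> tuple[np.ndarray, list[str]]:
    """log1p of the normalized matrix restricted to highly variable genes."""
    work = adata.copy()
    sc.pp.log1p(work)
    n_top = min(n_hvg, work.n_vars)
    if work.n_vars > n_top:
        sc.pp.highly_variable_genes(work, n_top_genes=n_top, flavor="seurat")
        work = work[:, work.var["highly_variable"]].copy()
    X = work.X
    if sp.issparse(X):
        X = np.asarray(X.todense())
    return np.asarray(X), list(work.var_names)


def _pca(X: np.ndarray, n_pcs: int, seed: int) -> tuple[np.ndarray, PCA]:
    n_comp = min(n_pcs, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    return pca.fit_transform(X), pca


def _knn_graph(pcs: np.ndarray, k: int) -> igraph.Graph:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = set()
    for i, neigh in enumerate(idx):
        for j in neigh[1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = igraph.Graph(n=len(pcs), edges=sorted(edges))
    return graph


def _louvain(graph: igraph.Graph, resolution: float, seed: int) -> np.ndarray:
    igraph.set_random_number_generator(_pyrandom.Random(seed))
    communities = graph.community_multilevel(resolution=resolution)
    membership = np.asarray(communities.membership)
    # relabel 0..K-1 by decreasing size; ties by original community id
    sizes = pd.Series(membership).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[m] for m in membership])


def cluster_cells(
    adata: ad.AnnData,
    n_pcs: int = 50,
    k_graph: int = 15,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
    n_hvg: int = DEFAULT_N_HVG,
) -> ClusterAssignment:
    """Louvain community detection in PCA space of the normalized matrix."""
    if adata.n_obs < k_graph + 1:
        raise InputError(f"need more than k_graph={k_graph} cells, got {adata.n_obs}")
    X, _ = _log1p_hvg_matrix(adata, n_hvg)
    pcs, _ = _pca(X, n_pcs, seed)
    graph = _knn_graph(pcs, k_graph)
    labels = _louvain(graph, resolution, seed)
    params = dict(
        n_pcs=n_pcs, k_graph=k_graph, resolution=resolution, seed=seed, n_hvg=n_hvg
    )
    return ClusterAssignment(labels=labels, params=params)


def scale_unit_interval(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each column to [0, 1]; constant columns map to all zeros."""
    out = table.astype(float).copy()
    for col in out.columns:
        lo, hi = out[col].min(), out[col].max()
        out[col] = 0.0 if hi == lo else (out[col] - lo) / (hi - lo)
    return out


def annotate_clusters(
    assignment: ClusterAssignment,
    adata: ad.AnnData,
    markers: MarkerTable,
    min_score: float = 0.5,
) -> ClusterAssignment:
    """Label clusters by their strongest scaled marker-program score.

    For each cluster and population the score is the mean, over the
    population's markers, of the cluster's mean expression scaled to
    [0, 1] across clusters. A cluster whose top score falls below
    ``min_score`` stays "unassigned".
    """
    if len(assignment.labels) != adata.n_obs:
        raise InputError("assignment and matrix are not aligned")
    X = adata.X
    if sp.issparse(X):
        X = np.asarray(X.todense())
    expr = pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names)
    cluster_means = expr.groupby(assignment.labels).mean()
    scaled = scale_unit_interval(cluster_means)

    scores = {}
    for population, genes in markers.markers.items():
        present = [g for g in genes if g in scaled.columns]
        missing = set(genes) - set(present)
        if missing:
            logger.warning("markers missing from matrix for %s: %s", population, sorted(missing))
        if not present:
            continue
        scores[population] = scaled[present].mean(axis=1)
    if not scores:
        raise InputError("no marker genes present in the matrix")
    score_table = pd.DataFrame(scores)
    identities = {}
    for cluster_id, row in score_table.iterrows():
        top = row.idxmax()
        identities[int(cluster_id)] = top if row[top] >= min_score else "unassigned"
    return ClusterAssignment(
        labels=assignment.labels, params=assignment.params, identities=identities
    )


def knn_transfer(
    reference: ad.AnnData,
    reference_assignment: ClusterAssignment,
    query: ad.AnnData,
    k: int = 15,
    n_pcs: int = 50,
    seed: int = 0,
    n_hvg: int = DEFAULT_N_HVG,
) -> np.ndarray:
    """Map query cells onto reference clusters via kNN in reference PCA space.

    The PCA basis (and highly variable gene selection) is fit on the
    reference; query cells are projected onto it and each receives the
    majority cluster among its k nearest reference cells, ties broken by
    the nearest single neighbour.
    """
    shared = reference.var_names.intersection(query.var_names)
    if len(shared) == 0:
        raise InputError("reference and query share no genes")
    ref = reference[:, shared].copy()
    qry = query[:, shared].copy()

    X_ref, hvg_genes = _log1p_hvg_matrix(ref, n_hvg)
    pcs_ref, pca = _pca(X_ref, n_pcs, seed)

    Xq = qry[:, hvg_genes].X
    if sp.issparse(Xq):
        Xq = np.asarray(Xq.todense())
    pcs_qry = pca.transform(np.log1p(np.asarray(Xq)))

    nn = NearestNeighbors(n_neighbors=k).fit(pcs_ref)
    _, idx = nn.kneighbors(pcs_qry)
    ref_labels = reference_assignment.labels
    out = np.empty(len(pcs_qry), dtype=int)
    for i, neigh in enumerate(idx):
        votes = pd.Series(ref_labels[neigh]).value_counts()
        top = votes[votes == votes.max()].index
        out[i] = ref_labels[neigh[0]] if len(top) > 1 else int(top[0])
    return out


def occupancy(
    identities: np.ndarray | pd.Series,
    genotypes: np.ndarray | pd.Series,
    focus: str,
) -> pd.DataFrame:
    """Per-genotype count/total/fraction of cells with the focus identity."""
    identities = pd.Series(np.asarray(identities, dtype=object), name="identity")
    genotypes = pd.Series(np.asarray(genotypes, dtype=object), name="genotype")
    if focus not in set(identities):
        raise InputError(f"identity {focus!r} not present")
    table = (
        pd.DataFrame({"identity": identities, "genotype": genotypes})
        .groupby("genotype")
        .agg(
            count=("identity", lambda s: int((s == focus).sum())),
            total=("identity", "size"),
        )
        .assign(fraction=lambda d: d["count"] / d["total"])
        .reset_index()
    )
    table.insert(1, "identity", focus)
    return table


def subcluster(
    adata: ad.AnnData,
    cell_mask: np.ndarray | pd.Series,
    resolution: float = SUBCLUSTER_RESOLUTION,
    seed: int = 0,
    n_pcs: int = 50,
    k_graph: int = 15,
    n_hvg: int = DEFAULT_N_HVG,
) -> ClusterAssignment:
    """Re-cluster a cell subset with recomputed HVGs and PCA."""
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.sum() == 0:
        raise InputError("empty cell subset")
    subset = adata[mask].copy()
    return cluster_cells(
        subset, n_pcs=n_pcs, k_graph=k_graph, resolution=resolution, seed=seed, n_hvg=n_hvg
    )


def rank_cluster_markers(
    adata: ad.AnnData,
    assignment: ClusterAssignment,
    max_padj: float = 0.05,
    min_log2fc: float = 0.25,
) -> dict[int, pd.DataFrame]:
    """Per-cluster upregulated genes vs the union of all other clusters.

    Wilcoxon rank-sum on log1p normalized data with Benjamini-Hochberg
    correction; returns genes with adjusted p < ``max_padj`` and log2
    fold-change > ``min_log2fc`` sorted by adjusted p. Clusters of one
    cell are excluded with a warning.
    """
    labels = pd.Series(assignment.labels, index=adata.obs_names)
    counts = labels.value_counts()
    if (counts > 1).sum() < 2:
        raise InputError("need at least two clusters with more than one cell")
    work = adata.copy()
    sc.pp.log1p(work)
    keep_clusters = counts[counts > 1].index
    dropped = counts[counts <= 1].index.tolist()
    if dropped:
        logger.warning("excluding singleton clusters from DE: %s", dropped)
    work = work[labels.isin(keep_clusters).values].copy()
    work.obs["cluster"] = pd.Categorical(
        labels.loc[work.obs_names].astype(int).astype(str)
    )
    sc.tl.rank_genes_groups(
        work, "cluster", method="wilcoxon", corr_method="benjamini-hochberg"
    )
    out: dict[int, pd.DataFrame] = {}
    for group in work.obs["cluster"].cat.categories:
        table = sc.get.rank_genes_groups_df(work, group=group)
        table = table.rename(
            columns={
                "names": "gene",
                "logfoldchanges": "log2fc",
                "pvals": "pval",
                "pvals_adj": "padj",
            }
        )
        table = table[(table["padj"] < max_padj) & (table["log2fc"] > min_log2fc)]
        out[int(group)] = table.sort_values("padj").reset_index(drop=True)[
            ["gene", "log2fc", "pval", "padj"]
        ]
    return out
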