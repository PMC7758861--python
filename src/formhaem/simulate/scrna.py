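"""Synthetic droplet scRNA-seq count matrices with planted artifacts.

The generator emulates a multi-population hematopoietic landscape: each
population has its own negative-binomial expression program with elevated
marker genes, cells draw log-normal library sizes, mitochondrial genes
(named with the mouse ``mt-`` prefix) take a per-cell fraction of the
library, and a configurable share of barcodes are planted doublets (sums
of two singlet profiles — a droplet containing two cells holds both cells'
molecules) or low-quality cells violating the QC thresholds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from formhaem.errors import ConfigurationError
from formhaem.truth import TruthBundle


@dataclass
class Population:
    """One cell population: name, per-genotype proportion, marker program."""

    name: str
    proportions: dict[str, float]
    marker_genes: list[str]
    marker_log_fc: float = 2.0  # log2 fold-change of markers over background

    def __post_init__(self) -> None:
        if self.marker_log_fc <= 0:
            raise ConfigurationError(f"{self.name}: marker_log_fc must be > 0")


@dataclass
class ScRnaScenario:
    """Study conditions for one simulated scRNA-seq sample."""

    populations: list[Population]
    n_cells_per_sample: int = 2000
    n_genes: int = 2000
    library_size_log_mean: float = 8.5  # ln scale; e^8.5 ~ 4900 UMIs
    library_size_log_sd: float = 0.35
    nb_dispersion: float = 2.0
    mito_fraction_mean: float = 0.05
    mito_fraction_sd: float = 0.02
    doublet_fraction: float = 0.0
    lowquality_fraction: float = 0.0
    n_mito_genes: int = 10
    lowquality_mito_fraction: float = 0.30
    lowquality_n_genes: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_sample < 1 or self.n_genes < 1:
            raise ConfigurationError("n_cells_per_sample and n_genes must be positive")
        if not (0 <= self.doublet_fraction < 1 and 0 <= self.lowquality_fraction < 1):
            raise ConfigurationError("doublet/lowquality fractions must be in [0, 1)")
        if self.doublet_fraction + self.lowquality_fraction >= 1:
            raise ConfigurationError("doublet_fraction + lowquality_fraction must be < 1")
        if not 0 <= self.mito_fraction_mean <= 1 or not 0 <= self.mito_fraction_sd <= 1:
            raise ConfigurationError("mito fraction parameters must be in [0, 1]")
        if not self.populations:
            raise ConfigurationError("at least one population required")
        genotypes = set(self.populations[0].proportions)
        all_markers: list[str] = []
        for pop in self.populations:
            if set(pop.proportions) != genotypes:
                raise ConfigurationError("all populations must list the same genotypes")
            all_markers.extend(pop.marker_genes)
        if len(all_markers) != len(set(all_markers)):
            raise ConfigurationError("marker gene lists must be disjoint across populations")
        for g in genotypes:
            total = sum(p.proportions[g] for p in self.populations)
            if abs(total - 1.0) > 1e-8:
                raise ConfigurationError(f"population proportions for {g} sum to {total}, not 1")
        if self.n_genes < len(all_markers) + self.n_mito_genes + 10:
            raise ConfigurationError("n_genes too small for the configured marker programs")

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.populations[0].proportions)


def _rng_for(seed: int, tag: str) -> np.random.Generator:
    # stable per-genotype stream (crc32, not the salted builtin hash)
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(tag.encode())]))


def _gene_table(scenario: ScRnaScenario) -> pd.DataFrame:
    names: list[str] = []
    marker_of: list[str] = []
    for pop in scenario.populations:
        names.extend(pop.marker_genes)
        marker_of.extend([pop.name] * len(pop.marker_genes))
    for i in range(scenario.n_mito_genes):
        names.append(f"mt-{i + 1}")
        marker_of.append("")
    n_background = scenario.n_genes - len(names)
    for i in range(n_background):
        names.append(f"Gene{i + 1:05d}")
        marker_of.append("")
    var = pd.DataFrame(index=pd.Index(names, name="gene"))
    var["mito"] = var.index.str.startswith("mt-")
    var["marker_of"] = marker_of
    return var


def _population_weights(
    scenario: ScRnaScenario, var: pd.DataFrame, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-population relative expression over non-mito genes (each sums to 1)."""
    nonmito = ~var["mito"].values
    base = rng.lognormal(0.0, 1.5, size=scenario.n_genes)
    base[~nonmito] = 0.0
    weights = {}
    gene_pos = {g: i for i, g in enumerate(var.index)}
    for pop in scenario.populations:
        w = base.copy()
        idx = [gene_pos[g] for g in pop.marker_genes]
        w[idx] *= 2.0 ** pop.marker_log_fc
        weights[pop.name] = w / w.sum()
    return weights


def _sample_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draw with mean mu and size (dispersion) r."""
    r = dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _singlet_profiles(
    scenario: ScRnaScenario,
    pops: np.ndarray,
    weights: dict[str, np.ndarray],
    mito_w: np.ndarray,
    rng: np.random.Generator,
    mito_fraction: np.ndarray | None = None,
    libsize_scale: float = 1.0,
    gene_mask: np.ndarray | None = None,
) -> np.ndarray:
    n = len(pops)
    lib = rng.lognormal(scenario.library_size_log_mean, scenario.library_size_log_sd, n)
    lib *= libsize_scale
    if mito_fraction is None:
        mito_fraction = np.clip(
            rng.normal(scenario.mito_fraction_mean, scenario.mito_fraction_sd, n), 0.0, 0.95
        )
    counts = np.zeros((n, scenario.n_genes), dtype=np.int64)
    for name in np.unique(pops):
        rows = np.where(pops == name)[0]
        w = weights[name]
        if gene_mask is not None:
            w = w * gene_mask
            w = w / w.sum()
        mu = np.outer(lib[rows] * (1.0 - mito_fraction[rows]), w)
        mu += np.outer(lib[rows] * mito_fraction[rows], mito_w)
        counts[rows] = _sample_counts(mu, scenario.nb_dispersion, rng)
    return counts


def generate_scrna(
    scenario: ScRnaScenario, genotype: str, sample: str | None = None
) -> tuple[ad.AnnData, TruthBundle]:
    """Generate one sample's raw UMI count matrix plus ground truth.

    Doublets are element-wise sums of two freshly drawn singlet profiles;
    low-quality cells get a planted high mitochondrial fraction and a
    reduced expressed-gene repertoire. Identical (scenario, genotype)
    inputs produce bit-identical output.
    """
    if genotype not in scenario.populations[0].proportions:
        raise ConfigurationError(f"genotype {genotype!r} has no population proportions")
    sample = sample or genotype
    rng = _rng_for(scenario.seed, genotype)
    # population expression programs are biology shared by all genotypes:
    # draw them from a genotype-independent stream so samples differ only
    # in composition and sampling noise, not in a spurious batch effect
    gene_rng = _rng_for(scenario.seed, "gene-programs")

    var = _gene_table(scenario)
    weights = _population_weights(scenario, var, gene_rng)
    mito_w = gene_rng.lognormal(0.0, 0.5, size=scenario.n_genes)
    mito_w[~var["mito"].values] = 0.0
    if mito_w.sum() > 0:
        mito_w /= mito_w.sum()

    n = scenario.n_cells_per_sample
    n_doublet = int(round(scenario.doublet_fraction * n))
    n_lowq = int(round(scenario.lowquality_fraction * n))
    n_singlet = n - n_doublet - n_lowq

    pop_names = [p.name for p in scenario.populations]
    props = np.array([p.proportions[genotype] for p in scenario.populations])

    singlet_pops = rng.choice(pop_names, size=n_singlet, p=props)
    singlets = _singlet_profiles(scenario, singlet_pops, weights, mito_w, rng)

    parent_pops = rng.choice(pop_names, size=2 * n_doublet, p=props)
    parents = _singlet_profiles(scenario, parent_pops, weights, mito_w, rng)
    doublets = parents[:n_doublet] + parents[n_doublet:]
    doublet_labels = np.array(
        [
            "+".join(sorted((a, b)))
            for a, b in zip(parent_pops[:n_doublet], parent_pops[n_doublet:])
        ],
        dtype=object,
    )

    lowq_pops = rng.choice(pop_names, size=n_lowq, p=props)
    nonmito_idx = np.where(~var["mito"].values)[0]
    keep = rng.choice(nonmito_idx, size=min(scenario.lowquality_n_genes, len(nonmito_idx)), replace=False)
    gene_mask = np.zeros(scenario.n_genes)
    gene_mask[keep] = 1.0
    lowq = _singlet_profiles(
        scenario,
        lowq_pops,
        weights,
        mito_w,
        rng,
        mito_fraction=np.full(n_lowq, scenario.lowquality_mito_fraction),
        libsize_scale=0.5,
        gene_mask=gene_mask,
    )

    counts = np.vstack([singlets, doublets, lowq])
    populations = np.concatenate([singlet_pops, doublet_labels, lowq_pops])
    is_doublet = np.r_[
        np.zeros(n_singlet, bool), np.ones(n_doublet, bool), np.zeros(n_lowq, bool)
    ]
    is_lowquality = np.r_[
        np.zeros(n_singlet + n_doublet, bool), np.ones(n_lowq, bool)
    ]

    order = rng.permutation(n)
    counts = counts[order]
    barcodes = [f"{sample}-CELL{i + 1:06d}" for i in range(n)]

    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    obs["sample"] = sample
    obs["genotype"] = genotype

    X = sp.csr_matrix(counts.astype(np.float64))
    adata = ad.AnnData(X=X, obs=obs, var=var.copy())
    adata.layers["counts"] = adata.X.copy()

    truth_cells = pd.DataFrame(
        {
            "population": populations[order],
            "is_doublet": is_doublet[order],
            "is_lowquality": is_lowquality[order],
            "sample": sample,
            "genotype": genotype,
        },
        index=obs.index,
    )
    return adata, TruthBundle(cells=truth_cells)


def default_hematopoietic_populations(
    hsc_fraction: dict[str, float] | None = None,
) -> list[Population]:
    """The seven marker-defined populations of the profiled bone marrow.

    Marker programs follow the annotation table used for cluster labelling
    (Procr for HSC; Dntt/Flt3 lymphoid; Irf8/Ms4a6c monocyte;
    Mpo/Elane/Ctsg neutrophil; Itga2b/Pf4/Vwf megakaryocyte;
    Gzmb/Cma3/Mcpt8 mast; Klf1/Gata1 erythroid), padded with synthetic
    program genes so each population is separable.
    """
    hsc_fraction = hsc_fraction or {"WT": 0.06}
    genotypes = list(hsc_fraction)
    named = {
        "HSC": ["Procr"],
        "Lymphoid": ["Dntt", "Flt3"],
        "Monocyte": ["Irf8", "Ms4a6c"],
        "Neutrophil": ["Mpo", "Elane", "Ctsg"],
        "Megakaryocyte": ["Itga2b", "Pf4", "Vwf"],
        "Mast": ["Gzmb", "Cma3", "Mcpt8"],
        "Erythroid": ["Klf1", "Gata1"],
    }
    pops = []
    names = list(named)
    for name in names:
        markers = named[name] + [f"{name}-prog{i}" for i in range(1, 21 - len(named[name]))]
        proportions = {}
        for g in genotypes:
            hsc = hsc_fraction[g]
            rest = (1.0 - hsc) / (len(names) - 1)
            proportions[g] = hsc if name == "HSC" else rest
        pops.append(Population(name, proportions, markers, marker_log_fc=2.0))
    return pops
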