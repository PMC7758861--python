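"""Stage runner binding the arms into reproducible, manifest-backed runs.

``run`` executes the selected stages in dependency order inside one
output directory: ``simulate`` writes all synthetic inputs (MTX count
matrices, FASTA/BED genome, VCF catalogs, CSV chemistry tables); the
analysis stages consume those files through the same readers a real
dataset would use and write CSV results. A :class:`RunManifest` records
the config snapshot, seeds, input checksums and per-stage record counts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import formhaem
from formhaem import chem as chemq
from formhaem import cluster as clu
from formhaem import io, qc, scores, signatures, spectra, variants
from formhaem.config import PipelineConfig, validate_config
from formhaem.errors import InputError
from formhaem.simulate import (
    ChemScenario,
    GenomeSpec,
    MutScenario,
    ScRnaScenario,
    generate_absorbance_trace,
    generate_gcms_batch,
    generate_genome,
    generate_mutation_catalogs,
    generate_scrna,
)
from formhaem.simulate.mutations import ArtifactRates
from formhaem.simulate.scrna import default_hematopoietic_populations

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                dict(
                    config=self.config,
                    version=self.version,
                    seed=self.seed,
                    input_checksums=self.input_checksums,
                    stage_counts=self.stage_counts,
                ),
                fh,
                indent=2,
                sort_keys=True,
                default=str,
            )


def _scrna_scenario(config: PipelineConfig) -> ScRnaScenario:
    block = config.scrna
    return ScRnaScenario(
        populations=default_hematopoietic_populations(block.hsc_fraction),
        n_cells_per_sample=block.n_cells_per_sample,
        n_genes=block.n_genes,
        doublet_fraction=block.doublet_fraction,
        lowquality_fraction=block.lowquality_fraction,
        lowquality_n_genes=min(300, block.n_genes // 4),
        seed=config.seed,
    )


def _signature_matrix(config: PipelineConfig) -> pd.DataFrame:
    if config.mut.signature_csv:
        return signatures.load_signatures(config.mut.signature_csv)
    return signatures.synthetic_signatures()


def _stage_simulate(config: PipelineConfig, outdir: str, manifest: RunManifest) -> None:
    counts: dict = {}
    scenario = _scrna_scenario(config)
    for genotype in scenario.genotypes:
        adata, truth = generate_scrna(scenario, genotype)
        gdir = os.path.join(outdir, "scrna", genotype)
        io.write_counts_mtx(adata, gdir)
        truth.cells.to_csv(os.path.join(gdir, "truth_cells.csv"))
        counts[f"scrna_cells_{genotype}"] = int(adata.n_obs)

    mut = config.mut
    genome_spec = GenomeSpec(
        n_chromosomes=mut.n_chromosomes,
        chromosome_length=mut.chromosome_length,
        gene_density=mut.gene_density,
        seed=config.seed,
    )
    genome, genes = generate_genome(genome_spec)
    genome.to_fasta(os.path.join(outdir, "genome.fa"))
    io.write_bed(genes, os.path.join(outdir, "genes.bed"))
    sigs = _signature_matrix(config)
    mut_scenario = MutScenario(
        sbs_mean=mut.sbs_mean,
        dbs_mean=mut.dbs_mean,
        indel_mean=mut.indel_mean,
        signature_weights=mut.signature_weights,
        n_genomes_per_genotype=mut.n_genomes_per_genotype,
        strand_bias_odds=mut.strand_bias_odds,
        artifact_rates=ArtifactRates(mut.artifact_rate, mut.artifact_rate, mut.artifact_rate),
        seed=config.seed,
    )
    records, truth = generate_mutation_catalogs(mut_scenario, genome, genes, sigs)
    vcf_dir = os.path.join(outdir, "vcf")
    os.makedirs(vcf_dir, exist_ok=True)
    group_map = {}
    for genome_id, frame in records.items():
        io.write_vcf(frame, os.path.join(vcf_dir, f"{genome_id}.vcf"))
        group_map[genome_id] = genome_id.rsplit("-g", 1)[0]
    with open(os.path.join(vcf_dir, "groups.json"), "w") as fh:
        json.dump(group_map, fh, indent=0)
    truth.variants.to_csv(os.path.join(vcf_dir, "truth_variants.csv"), index=False)
    counts["genomes"] = len(records)
    counts["variant_records"] = int(sum(len(f) for f in records.values()))

    chem_block = config.chem
    chem_scenario = ChemScenario(
        calib_levels_mg_per_l=chem_block.calib_levels_mg_per_l,
        n_replicates=chem_block.n_replicates,
        noise_cv=chem_block.noise_cv,
        group_true_means_uM=chem_block.group_true_means_uM,
        group_n=chem_block.group_n,
        seed=config.seed,
    )
    areas, chem_truth = generate_gcms_batch(chem_scenario)
    chem_dir = os.path.join(outdir, "chem")
    os.makedirs(chem_dir, exist_ok=True)
    areas.to_csv(os.path.join(chem_dir, "areas.csv"), index=False)
    chem_truth.concentrations.to_csv(os.path.join(chem_dir, "truth_conc.csv"), index=False)
    trace, _ = generate_absorbance_trace(
        baseline_slope=1e-5, reaction_slope=1e-3, noise_sd=0.002, seed=config.seed
    )
    trace.to_csv(os.path.join(chem_dir, "trace.csv"), index=False)
    counts["area_records"] = len(areas)
    manifest.stage_counts["simulate"] = counts


def _stage_sc_qc(config: PipelineConfig, outdir: str, manifest: RunManifest) -> None:
    thresholds = qc.QcThresholds(**config.qc.model_dump())
    doublet_cfg = qc.DoubletConfig(seed=config.seed, **config.doublet.model_dump())
    counts: dict = {}
    scrna_dir = os.path.join(outdir, "scrna")
    if not os.path.isdir(scrna_dir):
        raise InputError("sc-qc: no scrna inputs found; run the simulate stage first")
    for genotype in sorted(os.listdir(scrna_dir)):
        gdir = os.path.join(scrna_dir, genotype)
        adata = io.read_counts_mtx(gdir)
        clean, report = qc.run_qc_stage(adata, thresholds, doublet_cfg)
        out_gdir = os.path.join(outdir, "scrna_qc", genotype)
        io.write_counts_mtx(clean, out_gdir)
        report.per_cell.to_csv(os.path.join(out_gdir, "qc_report.csv"))
        report.per_sample.to_csv(os.path.join(out_gdir, "qc_summary.csv"), index=False)
        counts[genotype] = dict(input=int(adata.n_obs), retained=int(clean.n_obs))
    manifest.stage_counts["sc-qc"] = counts


def _read_clean_matrices(outdir: str):
    import anndata as ad

    qc_dir = os.path.join(outdir, "scrna_qc")
    if not os.path.isdir(qc_dir):
        raise InputError("sc-cluster: run sc-qc first")
    parts = []
    for genotype in sorted(os.listdir(qc_dir)):
        part = io.read_counts_mtx(os.path.join(qc_dir, genotype))
        parts.append(part)
    combined = ad.concat(parts, join="inner", merge="first")
    combined.obs_names_make_unique()
    return combined


def _stage_sc_cluster(config: PipelineConfig, outdir: str, manifest: RunManifest) -> None:
    adata = _read_clean_matrices(outdir)
    block = config.clustering
    assignment = clu.cluster_cells(
        adata, n_pcs=block.n_pcs, k_graph=block.k_graph,
        resolution=block.resolution, seed=config.seed, n_hvg=block.n_hvg,
    )
    marker_table = clu.MarkerTable(
        {
            "HSC": ["Procr"],
            "Lymphoid": ["Dntt", "Flt3"],
            "Monocyte": ["Irf8", "Ms4a6c"],
            "Neutrophil": ["Mpo", "Elane", "Ctsg"],
            "Megakaryocyte": ["Itga2b", "Pf4", "Vwf"],
            "Mast": ["Gzmb", "Cma3", "Mcpt8"],
            "Erythroid": ["Klf1", "Gata1"],
        }
    )
    labeled = clu.annotate_clusters(assignment, adata, marker_table)
    identities = labeled.identity_per_cell()
    out = pd.DataFrame(
        {
            "cluster": labeled.labels,
            "identity": identities,
            "genotype": adata.obs["genotype"].to_numpy(),
        },
        index=adata.obs_names,
    )
    out.to_csv(os.path.join(outdir, "cluster_assignments.csv"))
    if "HSC" in set(identities):
        occ = clu.occupancy(identities, adata.obs["genotype"].to_numpy(), "HSC")
        occ.to_csv(os.path.join(outdir, "hsc_occupancy.csv"), index=False)
    manifest.stage_counts["sc-cluster"] = dict(
        cells=int(adata.n_obs), clusters=int(labeled.n_clusters)
    )


def _stage_sc_score(config: PipelineConfig, outdir: str, manifest: RunManifest) -> None:
    if not config.genesets:
        logger.info("sc-score: no genesets configured, skipping")
        manifest.stage_counts["sc-score"] = dict(genesets=0)
        return
    adata = _read_clean_matrices(outdir)
    results = {}
    for name, path in config.genesets.items():
        geneset = scores.GeneSet.from_csv(path, name=name)
        results[name] = scores.module_score(adata, geneset).scores
    pd.DataFrame(results).to_csv(os.path.join(outdir, "module_scores.csv"))
    manifest.stage_counts["sc-score"] = dict(genesets=len(results))


def _stage_mutsig(config: PipelineConfig, outdir: str, manifest: RunManifest) -> None:
    vcf_dir = os.path.join(outdir, "vcf")
    if not os.path.isdir(vcf_dir):
        raise InputError("mutsig: no VCF inputs found; run the simulate stage first")
    with open(os.path.join(vcf_dir, "groups.json")) as fh:
        group_map = json.load(fh)
    paths = {
        gid: os.path.join(vcf_dir, f"{gid}.vcf")
        for gid in group_map
        if os.path.exists(os.path.join(vcf_dir, f"{gid}.vcf"))
    }
    genome = io.Genome.from_fasta(os.path.join(outdir, "genome.fa"))
    genes = io.read_bed(os.path.join(outdir, "genes.bed"))

    records = variants.read_variants(paths, group_map)
    fcfg = variants.FilterConfig(
        min_depth=config.filter.min_depth,
        min_vaf=config.filter.min_vaf,
        excluded_filter_flags=frozenset(config.filter.excluded_filter_flags),
        exclude_multiallelic=config.filter.exclude_multiallelic,
    )
    kept, filter_report = variants.filter_variants(records, fcfg)
    catalog = variants.classify_variants(kept)

    per_genome, per_group = spectra.burden_table(catalog)
    per_genome.to_csv(os.path.join(outdir, "burden_per_genome.csv"), index=False)
    per_group.to_csv(os.path.join(outdir, "burden_per_group.csv"), index=False)
    filter_report.to_csv(os.path.join(outdir, "filter_report.csv"), index=False)

    groups = sorted(set(group_map.values()))
    profiles, labels = [], []
    for gid, sub in catalog.sbs.groupby("genome"):
        profiles.append(spectra.sbs_context_profile(sub, genome, label=gid))
        labels.append(group_map[gid])
    if profiles:
        agg = spectra.aggregate_profiles(profiles, labels)
        pd.DataFrame({g: p.to_series() for g, p in agg.items()}).to_csv(
            os.path.join(outdir, "sbs_profiles.csv")
        )
        sigs = _signature_matrix(config)
        total = spectra.aggregate_profiles(profiles)["all"]
        spectra.cosine_rank(total, sigs).to_csv(
            os.path.join(outdir, "cosine_similarity.csv"), index=False
        )
        spectra.strand_bias(catalog, genome, genes).to_csv(
            os.path.join(outdir, "strand_bias.csv"), index=False
        )
    if groups:
        reference = groups[-1] if "WT" not in groups else "WT"
        try:
            spectra.relative_burden(catalog, reference).to_csv(
                os.path.join(outdir, "relative_burden.csv"), index=False
            )
        except InputError as exc:
            logger.warning("relative burden skipped: %s", exc)
    manifest.stage_counts["mutsig"] = dict(
        records=len(records), kept=len(kept),
        sbs=len(catalog.sbs), dbs=len(catalog.dbs), indels=len(catalog.indels),
    )


def _stage_chem(config: PipelineConfig, outdir: str, manifest: RunManifest) -> None:
    chem_dir = os.path.join(outdir, "chem")
    areas_path = os.path.join(chem_dir, "areas.csv")
    if not os.path.exists(areas_path):
        raise InputError("chem: no area table found; run the simulate stage first")
    areas = pd.read_csv(areas_path)
    curve = chemq.fit_calibration(areas[areas["role"] == "standard"])
    samples = chemq.quantify_samples(areas[areas["role"] == "sample"], curve)
    samples.to_csv(os.path.join(outdir, "concentrations.csv"), index=False)
    folds = chemq.group_fold_change(samples, config.chem.reference_group)
    folds.to_csv(os.path.join(outdir, "fold_changes.csv"), index=False)
    max_cv, ok = chemq.calibration_precision(curve, config.chem.precision_bound)
    trace_path = os.path.join(chem_dir, "trace.csv")
    activity = None
    if os.path.exists(trace_path):
        trace = pd.read_csv(trace_path)
        activity = chemq.aldh_activity(trace, substrate_addition_time=300.0)
    summary = dict(
        slope=curve.slope, intercept=curve.intercept, r_squared=curve.r_squared,
        max_level_cv=max_cv, precision_ok=bool(ok), activity_uM_min_mg=activity,
    )
    with open(os.path.join(outdir, "calibration_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest.stage_counts["chem"] = dict(
        standards=int((areas["role"] == "standard").sum()),
        samples=int((areas["role"] == "sample").sum()),
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "sc-qc": _stage_sc_qc,
    "sc-cluster": _stage_sc_cluster,
    "sc-score": _stage_sc_score,
    "mutsig": _stage_mutsig,
    "chem": _stage_chem,
}


def run(config: PipelineConfig | dict | str | None, outdir: str) -> RunManifest:
    """Execute the configured stages and write ``manifest.json``."""
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(
        config=config.model_dump(), version=formhaem.__version__, seed=config.seed
    )
    for stage in config.stages:
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](config, outdir, manifest)
    for name in ("genome.fa", "genes.bed"):
        path = os.path.join(outdir, name)
        if os.path.exists(path):
            manifest.input_checksums[name] = io.sha256_file(path)
    manifest.write(os.path.join(outdir, "manifest.json"))
    return manifest
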