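"""Mutational-spectrum arm, end to end on synthetic data.

Generates a small reference genome with gene annotation, plants SBS/DBS/
indel catalogs at genotype-specific burdens (with sequencing artifacts
and a transcriptional strand bias), then runs the variant filter,
adjacency classification, burden tables, 96-channel profiles, cosine
ranking against the signature collection, and strand-bias statistics.
"""

import pandas as pd

from formhaem.signatures import synthetic_signatures
from formhaem.simulate import GenomeSpec, MutScenario, generate_genome, generate_mutation_catalogs
from formhaem.simulate.mutations import ArtifactRates
from formhaem.spectra import (
    aggregate_profiles,
    burden_table,
    cosine_rank,
    relative_burden,
    sbs_context_profile,
    strand_bias,
)
from formhaem.variants import FilterConfig, classify_variants, filter_variants, records_from_frame

genome, genes = generate_genome(
    GenomeSpec(n_chromosomes=2, chromosome_length=300_000, gene_density=0.4, seed=0)
)
signatures = synthetic_signatures()

scenario = MutScenario(
    sbs_mean={"WT": 100.0, "DKO": 300.0},
    dbs_mean={"WT": 0.5, "DKO": 4.0},
    indel_mean={"WT": 20.0, "DKO": 40.0},
    signature_weights={"clocklike-cpg": 0.5, "ta-heavy": 0.3, "flat": 0.2},
    n_genomes_per_genotype={"WT": 8, "DKO": 8},
    strand_bias_odds={"T>A": 3.0},
    artifact_rates=ArtifactRates(5.0, 5.0, 5.0),
    seed=0,
)
records, truth = generate_mutation_catalogs(scenario, genome, genes, signatures)
print(f"generated {sum(len(f) for f in records.values())} variant records "
      f"across {len(records)} genomes")

frames = [
    records_from_frame(frame, genome_id, genome_id.split("-")[0])
    for genome_id, frame in records.items()
]
kept, filter_report = filter_variants(pd.concat(frames, ignore_index=True), FilterConfig())
print("\nfilter report (rejections by first matching rule):")
print(filter_report.to_string(index=False))

catalog = classify_variants(kept)
per_genome, per_group = burden_table(catalog)
print("\nper-group burdens (mean +/- SEM):")
print(per_group.to_string(index=False))

sbs_means = per_group[per_group["kind"] == "sbs"].set_index("genotype")["mean"]
print(f"\nSBS fold change DKO/WT: {sbs_means['DKO'] / sbs_means['WT']:.2f}")

profiles, labels = [], []
for genome_id, sub in catalog.sbs.groupby("genome"):
    profiles.append(sbs_context_profile(sub, genome, label=genome_id))
    labels.append(genome_id.split("-")[0])
total = aggregate_profiles(profiles)["all"]
print("\ncosine similarity of the pooled profile to each signature:")
print(cosine_rank(total, signatures).to_string(index=False))

print("\nrelative burden (per-genome counts / WT mean), head:")
print(relative_burden(catalog, "WT").head().to_string(index=False))

print("\ntranscriptional strand bias (coding vs template pyrimidine):")
print(strand_bias(catalog, genome, genes).to_string(index=False))
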