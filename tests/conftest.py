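import numpy as np
import pytest

from formhaem.signatures import synthetic_signatures
from formhaem.simulate import (
    GenomeSpec,
    MutScenario,
    ScRnaScenario,
    generate_genome,
    generate_mutation_catalogs,
    generate_scrna,
)
from formhaem.simulate.mutations import ArtifactRates
from formhaem.simulate.scrna import Population, default_hematopoietic_populations


@pytest.fixture(scope="session")
def hemato_sample():
    """1,000-cell hematopoietic sample with 5% doublets and 5% low-quality cells."""
    scenario = ScRnaScenario(
        populations=default_hematopoietic_populations({"WT": 0.06}),
        n_cells_per_sample=1000,
        n_genes=1500,
        doublet_fraction=0.05,
        lowquality_fraction=0.05,
        lowquality_n_genes=150,
        seed=7,
    )
    adata, truth = generate_scrna(scenario, "WT")
    return adata, truth, scenario


@pytest.fixture(scope="session")
def two_population_sample():
    """Two well-separated populations, 500 cells each."""
    pops = [
        Population("A", {"WT": 0.5}, [f"A-m{i}" for i in range(50)], marker_log_fc=2.0),
        Population("B", {"WT": 0.5}, [f"B-m{i}" for i in range(50)], marker_log_fc=2.0),
    ]
    scenario = ScRnaScenario(
        populations=pops, n_cells_per_sample=1000, n_genes=1000, seed=11
    )
    return generate_scrna(scenario, "WT")


@pytest.fixture(scope="session")
def small_genome():
    spec = GenomeSpec(n_chromosomes=2, chromosome_length=150_000, gene_density=0.4, seed=1)
    return generate_genome(spec)


@pytest.fixture(scope="session")
def signature_matrix():
    return synthetic_signatures()


@pytest.fixture(scope="session")
def mutation_batch(small_genome, signature_matrix):
    """Two-genotype catalog batch with planted artifacts and strand bias."""
    genome, genes = small_genome
    scenario = MutScenario(
        sbs_mean={"WT": 100.0, "DKO": 300.0},
        dbs_mean={"WT": 0.5, "DKO": 4.0},
        indel_mean={"WT": 20.0, "DKO": 40.0},
        signature_weights={"clocklike-cpg": 0.5, "ta-heavy": 0.3, "flat": 0.2},
        n_genomes_per_genotype={"WT": 4, "DKO": 4},
        strand_bias_odds={"T>A": 3.0},
        artifact_rates=ArtifactRates(5.0, 5.0, 5.0),
        seed=3,
    )
    records, truth = generate_mutation_catalogs(scenario, genome, genes, signature_matrix)
    return records, truth, scenario


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
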