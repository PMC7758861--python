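"""Random reference genomes with non-overlapping stranded gene annotation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from formhaem.errors import ConfigurationError
from formhaem.io import Genome

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeSpec:
    """Shape of a synthetic genome.

    ``gene_density`` is the fraction of each chromosome covered by genes;
    genes never overlap and carry random strands, emulating the gene-body
    intervals used for transcriptional strand assignment.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    gene_density: float = 0.4
    mean_gene_length: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        if self.chromosome_length < 3:
            raise ConfigurationError("chromosome_length must be >= 3")
        if not 0.0 <= self.gene_density < 1.0:
            raise ConfigurationError("gene_density must be in [0, 1)")
        if self.mean_gene_length < 1:
            raise ConfigurationError("mean_gene_length must be positive")


def generate_genome(spec: GenomeSpec) -> tuple[Genome, pd.DataFrame]:
    """Generate uniform-random chromosome sequences and a BED-style gene table.

    Returns the genome and a DataFrame with ``chrom, start, end, name,
    strand`` (0-based half-open intervals). Gene lengths are exponential
    around ``mean_gene_length``; intergenic gaps are sized so that the
    expected covered fraction equals ``gene_density``.
    """
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    rows = []
    gene_counter = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        seq = rng.choice(_BASES, size=spec.chromosome_length)
        sequences[chrom] = "".join(seq)
        if spec.gene_density > 0:
            # expected gap so genes cover gene_density of the chromosome
            mean_gap = spec.mean_gene_length * (1.0 - spec.gene_density) / spec.gene_density
            pos = int(rng.exponential(mean_gap))
            while True:
                length = max(60, int(rng.exponential(spec.mean_gene_length)))
                end = pos + length
                if end >= spec.chromosome_length:
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((chrom, pos, end, f"gene{gene_counter:05d}", strand))
                gene_counter += 1
                pos = end + 1 + int(rng.exponential(mean_gap))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return Genome(sequences), genes
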