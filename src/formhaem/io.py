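"""Shared format readers and writers.

Conventions (centralised here so callers never juggle coordinate systems):

* VCF positions are 1-based (VCF v4.2); DP and AF live in INFO.
* BED is 0-based half-open, six columns (chrom, start, end, name, score,
  strand).
* Count matrices are MatrixMarket ``matrix.mtx`` plus ``barcodes.tsv`` and
  ``features.tsv`` (feature id, feature name, mito flag column).
"""

from __future__ import annotations

import os
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class Genome:
    """In-memory reference genome with 0-based half-open ``fetch``."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {str(k): str(v).upper() for k, v in sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        import pyfaidx

        fasta = pyfaidx.Fasta(path)
        return cls({name: str(fasta[name][:]) for name in fasta.keys()})

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def write_bed(genes: pd.DataFrame, path: str) -> None:
    """Write a BED6 gene annotation (columns chrom, start, end, name, strand)."""
    out = genes.copy()
    if "score" not in out.columns:
        out["score"] = 0
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    genes = pd.read_csv(path, sep="\t", header=None, names=cols)
    return genes


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">
##INFO=<ID=AF,Number=A,Type=Float,Description="Variant allele fraction">
##FILTER=<ID=normal_artifact,Description="Evidence in the matched normal">
"""


def write_vcf(records: pd.DataFrame, path: str) -> None:
    """Write variant rows as a VCF v4.2 text file.

    Expects columns ``chrom, pos, ref, alt, depth, af, filter`` with ``pos``
    1-based and ``alt`` possibly comma-joined for multiallelic sites.
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom in sorted(records["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in records.sort_values(["chrom", "pos"]).itertuples():
            filt = row.filter if getattr(row, "filter", "PASS") else "PASS"
            af = ",".join(f"{a:.4f}" for a in np.atleast_1d(row.af))
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\t"
                f"{filt}\tDP={int(row.depth)};AF={af}\n"
            )


def write_counts_mtx(adata: ad.AnnData, outdir: str) -> None:
    """Write an AnnData's raw counts as MTX + barcodes/features TSVs."""
    os.makedirs(outdir, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    counts = sp.csr_matrix(counts)
    # genes x cells on disk, 10x convention
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), counts.T)
    obs = adata.obs.reset_index().rename(columns={"index": "barcode"})
    obs.to_csv(os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False)
    var = adata.var.reset_index().rename(columns={"index": "gene"})
    var.to_csv(os.path.join(outdir, "features.tsv"), sep="\t", index=False)


def read_counts_mtx(indir: str) -> ad.AnnData:
    """Read MTX + TSV written by :func:`write_counts_mtx` into an AnnData."""
    counts = scipy.io.mmread(os.path.join(indir, "matrix.mtx")).T.tocsr()
    obs = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t").set_index("barcode")
    var = pd.read_csv(os.path.join(indir, "features.tsv"), sep="\t").set_index("gene")
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    adata = ad.AnnData(X=counts.astype(np.float64), obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    return adata


def sha256_file(path: str) -> str:
    import hashlib

    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()
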