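"""Mutational-spectrum summaries of classified catalogs.

96-channel pyrimidine-convention SBS profiles, per-group aggregation,
burden tables (mean ± SEM), relative burdens against a reference group,
cosine-similarity ranking against a signature matrix, transcriptional
strand bias, and indel size histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from formhaem.contexts import CHANNELS_96, CHANNEL_INDEX, COMPLEMENT, PYRIMIDINES, SUB_TYPES, channel_of
from formhaem.errors import InputError
from formhaem.io import Genome
from formhaem.variants import MutationCatalog

logger = logging.getLogger(__name__)


@dataclass
class SbsProfile:
    """Ordered 96-channel count vector."""

    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise InputError("an SBS profile has exactly 96 channels")
        if (self.counts < 0).any():
            raise InputError("channel counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise InputError("cannot normalize an empty profile")
        return self.counts / self.total

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS_96), name=self.label)


def sbs_context_profile(
    sbs: pd.DataFrame | MutationCatalog, genome: Genome, label: str = ""
) -> SbsProfile:
    """Build the 96-channel profile of a catalog's substitutions.

    Each substitution is assigned to the pyrimidine base of the mutated
    pair: purine-reference events are reverse-complemented together with
    their flanking context. Sites at contig edges are skipped with a
    warning; a reference mismatch raises.
    """
    if isinstance(sbs, MutationCatalog):
        sbs = sbs.sbs
    counts = np.zeros(96)
    skipped = 0
    for r in sbs.itertuples():
        pos0 = int(r.pos) - 1
        seq = genome.sequences[str(r.chrom)]
        if pos0 < 1 or pos0 >= len(seq) - 1:
            skipped += 1
            continue
        triplet = seq[pos0 - 1 : pos0 + 2]
        if triplet[1] != r.ref:
            raise InputError(
                f"reference mismatch at {r.chrom}:{r.pos}: genome has {triplet[1]}, record {r.ref}"
            )
        counts[CHANNEL_INDEX[channel_of(triplet, r.alt)]] += 1
    if skipped:
        logger.warning("skipped %d substitutions at contig edges", skipped)
    return SbsProfile(counts=counts, label=label)


def aggregate_profiles(
    profiles: list[SbsProfile], grouping: list[str] | None = None, normalize: bool = False
) -> dict[str, SbsProfile]:
    """Element-wise sum of profiles per group (optionally as frequencies)."""
    grouping = grouping if grouping is not None else ["all"] * len(profiles)
    if len(grouping) != len(profiles):
        raise InputError("one group label per profile required")
    out: dict[str, SbsProfile] = {}
    for group in dict.fromkeys(grouping):
        total = np.zeros(96)
        for profile, g in zip(profiles, grouping):
            if g == group:
                total += profile.counts
        if normalize and total.sum() > 0:
            total = total / total.sum()
        out[group] = SbsProfile(counts=total, label=str(group))
    return out


def burden_table(catalog: MutationCatalog) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome SBS/DBS/indel counts and per-group mean ± SEM."""
    per_genome = catalog.counts_per_genome()
    if per_genome.empty:
        raise InputError("no genomes in catalog")
    rows = []
    for genotype, group in per_genome.groupby("genotype"):
        n = len(group)
        for kind in ("sbs", "dbs", "indel"):
            values = group[kind].to_numpy(dtype=float)
            rows.append(
                dict(
                    genotype=genotype,
                    kind=kind,
                    n_genomes=n,
                    mean=float(values.mean()),
                    sem=float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
                )
            )
    return per_genome, pd.DataFrame(rows)


def _sbs_type(ref: str, alt: str) -> str:
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def sbs_type_counts(sbs: pd.DataFrame) -> pd.DataFrame:
    """Per-genome counts of the six pyrimidine substitution types."""
    work = sbs.copy()
    work["type"] = [_sbs_type(r, a) for r, a in zip(work["ref"], work["alt"])]
    table = (
        work.pivot_table(index=["genome", "genotype"], columns="type", aggfunc="size", fill_value=0)
        .reindex(columns=list(SUB_TYPES), fill_value=0)
        .reset_index()
    )
    table.columns.name = None
    return table


def relative_burden(
    catalog: MutationCatalog, reference_group: str, per_channel: bool = False,
    genome: Genome | None = None,
) -> pd.DataFrame:
    """Per-genome substitution counts normalized to the reference-group mean.

    By default the six pyrimidine substitution types are used; with
    ``per_channel=True`` (requires ``genome``) all 96 channels are.
    Types with zero reference mean are reported as null with a warning.
    """
    if per_channel:
        if genome is None:
            raise InputError("per-channel relative burden requires the genome")
        frames = []
        for genome_id, group in catalog.sbs.groupby("genome"):
            profile = sbs_context_profile(group, genome, label=genome_id)
            row = profile.to_series()
            row["genome"] = genome_id
            row["genotype"] = group["genotype"].iloc[0]
            frames.append(row)
        table = pd.DataFrame(frames).set_index(["genome", "genotype"]).astype(float)
    else:
        table = sbs_type_counts(catalog.sbs).set_index(["genome", "genotype"]).astype(float)

    ref_rows = table.index.get_level_values("genotype") == reference_group
    if not ref_rows.any():
        raise InputError(f"reference group {reference_group!r} has no genomes")
    ref_mean = table[ref_rows].mean(axis=0)
    out = table.copy()
    for col in table.columns:
        if ref_mean[col] == 0:
            logger.warning("reference mean for %s is zero; reporting null", col)
            out[col] = np.nan
        else:
            out[col] = table[col] / ref_mean[col]
    return out.reset_index()


def cosine_rank(profile: SbsProfile, signatures: pd.DataFrame) -> pd.DataFrame:
    """Cosine similarity of a profile to each signature, sorted descending."""
    if list(signatures.index) != list(CHANNELS_96):
        raise InputError("signature matrix channel order mismatch")
    a = profile.counts
    norm_a = np.linalg.norm(a)
    if norm_a == 0:
        raise InputError("cannot rank a zero profile")
    rows = []
    for sig in signatures.columns:
        b = signatures[sig].to_numpy(dtype=float)
        denom = norm_a * np.linalg.norm(b)
        rows.append(dict(signature=sig, cosine=float(a @ b / denom) if denom else 0.0))
    return (
        pd.DataFrame(rows).sort_values("cosine", ascending=False).reset_index(drop=True)
    )


def strand_bias(
    catalog: MutationCatalog | pd.DataFrame, genome: Genome, genes: pd.DataFrame
) -> pd.DataFrame:
    """Transcriptional strand bias per substitution type.

    Each genic substitution is assigned by whether the pyrimidine of the
    mutated pair lies on the gene's coding strand or its template
    (transcribed) strand; intergenic sites and sites inside genes on both
    strands are unassigned. Reports counts, the coding/template ratio and
    a two-sided binomial p-value against 0.5.
    """
    sbs = catalog.sbs if isinstance(catalog, MutationCatalog) else catalog
    if genes is None or not {"chrom", "start", "end", "strand"}.issubset(genes.columns):
        raise InputError("gene annotation needs chrom/start/end/strand columns")

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("start")
        by_chrom[str(chrom)] = (
            sub["start"].to_numpy(), sub["end"].to_numpy(),
            sub["strand"].to_numpy(dtype=object),
        )

    def gene_strand(chrom: str, pos0: int) -> str | None:
        """'+', '-', 'both', or None for the gene(s) covering pos0."""
        if chrom not in by_chrom:
            return None
        starts, ends, strands = by_chrom[chrom]
        hits = strands[(starts <= pos0) & (pos0 < ends)]
        if len(hits) == 0:
            return None
        unique = set(hits)
        return hits[0] if len(unique) == 1 else "both"

    tallies = {t: {"coding": 0, "template": 0, "unassigned": 0} for t in SUB_TYPES}
    for r in sbs.itertuples():
        sub_type = _sbs_type(r.ref, r.alt)
        pyr_strand = "+" if r.ref in PYRIMIDINES else "-"
        gstrand = gene_strand(str(r.chrom), int(r.pos) - 1)
        if gstrand in (None, "both"):
            tallies[sub_type]["unassigned"] += 1
        elif gstrand == pyr_strand:
            tallies[sub_type]["coding"] += 1
        else:
            tallies[sub_type]["template"] += 1

    rows = []
    for sub_type in SUB_TYPES:
        coding = tallies[sub_type]["coding"]
        template = tallies[sub_type]["template"]
        total = coding + template
        rows.append(
            dict(
                type=sub_type,
                coding=coding,
                template=template,
                unassigned=tallies[sub_type]["unassigned"],
                ratio=coding / template if template else np.inf if coding else np.nan,
                p_value=binomtest(coding, total, 0.5).pvalue if total else np.nan,
            )
        )
    return pd.DataFrame(rows)


def indel_size_distribution(catalog: MutationCatalog) -> pd.DataFrame:
    """Histogram of signed indel lengths per genotype group."""
    if catalog.indels.empty:
        return pd.DataFrame(columns=["genotype", "length", "count"])
    return (
        catalog.indels.groupby(["genotype", "length"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["genotype", "length"])
        .reset_index(drop=True)
    )
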