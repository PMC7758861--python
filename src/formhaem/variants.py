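"""Somatic variant records: reading, filtering, and SBS/DBS/indel classification.

Variants arrive as caller output (VCF v4.2 with DP and AF). Filtering
keeps clonal, well-supported calls: depth >= 20, allele fraction >= 0.3,
no excluded FILTER flag, and no multiallelic sites (all configurable).
Classification merges maximal runs of adjacent same-genome substitutions
into tandem doublets (DBS), counts isolated substitutions as SBS, and
assigns length-changing alleles to indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from formhaem.errors import InputError

RECORD_COLUMNS = [
    "chrom", "pos", "ref", "alt", "depth", "af", "filter",
    "genome", "genotype", "multiallelic", "usable",
]


@dataclass
class FilterConfig:
    min_depth: int = 20
    min_vaf: float = 0.3
    excluded_filter_flags: frozenset = frozenset({"normal_artifact"})
    exclude_multiallelic: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 0 or not 0 <= self.min_vaf <= 1:
            raise InputError("min_depth >= 0 and 0 <= min_vaf <= 1 required")
        self.excluded_filter_flags = frozenset(self.excluded_filter_flags)


def records_from_frame(
    frame: pd.DataFrame, genome_id: str, genotype: str
) -> pd.DataFrame:
    """Expand generator/VCF-style rows into one record per ALT allele."""
    rows = []
    for r in frame.itertuples():
        alts = str(r.alt).split(",")
        afs = np.atleast_1d(r.af)
        multi = len(alts) > 1
        for i, alt in enumerate(alts):
            af = float(afs[i]) if i < len(afs) else float(afs[-1])
            filters = str(getattr(r, "filter", "PASS") or "PASS")
            flag_set = set() if filters in ("PASS", ".", "") else set(filters.split(";"))
            rows.append(
                dict(
                    chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=alt,
                    depth=int(r.depth), af=af, filter=";".join(sorted(flag_set)),
                    genome=genome_id, genotype=genotype, multiallelic=multi,
                    usable=True,
                )
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def read_variants(
    paths: dict[str, str], group_map: dict[str, str]
) -> pd.DataFrame:
    """Read VCF files into the record table (one row per ALT allele).

    ``paths`` maps genome id to VCF path; ``group_map`` maps genome id to
    genotype group. Records missing DP or AF are flagged unusable.
    """
    from cyvcf2 import VCF

    frames = []
    for genome_id, path in paths.items():
        genotype = group_map.get(genome_id, "")
        rows = []
        try:
            vcf = VCF(path)
        except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
            raise InputError(f"cannot parse {path}: {exc}") from exc
        for rec in vcf:
            depth = rec.INFO.get("DP")
            af = rec.INFO.get("AF")
            usable = depth is not None and af is not None
            alts = rec.ALT or []
            multi = len(alts) > 1
            afs = np.atleast_1d(af if af is not None else np.nan)
            filters = rec.FILTER  # None means PASS in cyvcf2
            flag_set = set() if not filters else set(str(filters).split(";"))
            for i, alt in enumerate(alts):
                rows.append(
                    dict(
                        chrom=str(rec.CHROM), pos=int(rec.POS), ref=str(rec.REF),
                        alt=str(alt), depth=int(depth) if depth is not None else -1,
                        af=float(afs[i]) if i < len(afs) else float(afs[-1]),
                        filter=";".join(sorted(flag_set)),
                        genome=genome_id, genotype=genotype,
                        multiallelic=multi, usable=usable,
                    )
                )
        frames.append(pd.DataFrame(rows, columns=RECORD_COLUMNS))
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(frames, ignore_index=True)


REJECTION_ORDER = ("multiallelic", "excluded_flag", "low_depth", "low_vaf", "unusable")


def filter_variants(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep clonal well-supported records; report rejections by first rule.

    Rule order mirrors the method description: multiallelic exclusion,
    excluded FILTER flags, then the depth and allele-fraction bounds
    (both inclusive).
    """
    config = config or FilterConfig()
    if records.empty:
        return records.copy(), pd.DataFrame({"reason": [], "count": []})
    excluded = config.excluded_filter_flags
    reasons = pd.Series("", index=records.index, dtype=object)

    flagged = records["filter"].fillna("").apply(
        lambda s: bool(set(s.split(";")) & excluded) if s else False
    )
    unusable = ~records["usable"].astype(bool)
    checks = [
        ("multiallelic", records["multiallelic"].astype(bool) & config.exclude_multiallelic),
        ("excluded_flag", flagged),
        ("low_depth", records["depth"] < config.min_depth),
        ("low_vaf", records["af"] < config.min_vaf),
        ("unusable", unusable),
    ]
    for reason, mask in checks:
        hit = mask & (reasons == "")
        reasons[hit] = reason
    kept = records[reasons == ""].copy()
    report = (
        reasons[reasons != ""]
        .value_counts()
        .rename_axis("reason")
        .reset_index(name="count")
    )
    return kept, report


@dataclass
class MutationCatalog:
    """Classified events per genome: SBS, DBS and indels."""

    sbs: pd.DataFrame    # chrom, pos, ref, alt, genome, genotype
    dbs: pd.DataFrame    # chrom, pos, ref, alt (dinucleotides), genome, genotype
    indels: pd.DataFrame  # chrom, pos, length (signed), kind, genome, genotype
    n_source_records: int = 0

    def genomes(self) -> list[str]:
        ids = set(self.sbs["genome"]) | set(self.dbs["genome"]) | set(self.indels["genome"])
        return sorted(ids)

    def counts_per_genome(self, groups: dict[str, str] | None = None) -> pd.DataFrame:
        genomes = self.genomes()
        table = pd.DataFrame(index=pd.Index(genomes, name="genome"))
        for name, events in (("sbs", self.sbs), ("dbs", self.dbs), ("indel", self.indels)):
            table[name] = events.groupby("genome").size().reindex(genomes).fillna(0).astype(int)
        genotype = {}
        for events in (self.sbs, self.dbs, self.indels):
            genotype.update(dict(zip(events["genome"], events["genotype"])))
        table["genotype"] = [groups.get(g) if groups else genotype.get(g, "") for g in genomes]
        return table.reset_index()


def classify_variants(records: pd.DataFrame) -> MutationCatalog:
    """Classify filtered records into SBS, DBS and indel events.

    Within each genome, maximal runs of adjacent single-nucleotide
    substitutions on one chromosome merge into tandem doublets
    left-to-right; a trailing unpaired substitution stays an SBS.
    Length-changing alleles become indels of the net length; equal-length
    multi-base substitutions of length two are DBS directly.
    """
    sbs_rows, dbs_rows, indel_rows = [], [], []
    if records.empty:
        empty_sbs = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "genome", "genotype"])
        empty_indel = pd.DataFrame(
            columns=["chrom", "pos", "length", "kind", "genome", "genotype"]
        )
        return MutationCatalog(sbs=empty_sbs, dbs=empty_sbs.copy(), indels=empty_indel)

    dup = records.duplicated(subset=["genome", "chrom", "pos"], keep=False)
    if dup.any():
        sites = records.loc[dup, ["genome", "chrom", "pos"]].drop_duplicates()
        raise InputError(f"overlapping records at positions: {sites.to_dict('records')}")

    for (genome_id, genotype), group in records.groupby(["genome", "genotype"], sort=True):
        snvs = group[(group["ref"].str.len() == 1) & (group["alt"].str.len() == 1)]
        others = group.drop(snvs.index)
        for r in others.itertuples():
            lref, lalt = len(r.ref), len(r.alt)
            if lref == lalt:
                if lref == 2:
                    dbs_rows.append(
                        dict(chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt,
                             genome=genome_id, genotype=genotype)
                    )
                else:  # complex same-length substitution: count as net-0 indel
                    indel_rows.append(
                        dict(chrom=r.chrom, pos=r.pos, length=0, kind="complex",
                             genome=genome_id, genotype=genotype)
                    )
            else:
                net = lalt - lref
                indel_rows.append(
                    dict(
                        chrom=r.chrom, pos=r.pos, length=net,
                        kind="insertion" if net > 0 else "deletion",
                        genome=genome_id, genotype=genotype,
                    )
                )
        for chrom, chrom_snvs in snvs.groupby("chrom"):
            chrom_snvs = chrom_snvs.sort_values("pos")
            run: list = []
            prev_pos = None
            for r in chrom_snvs.itertuples():
                if prev_pos is not None and r.pos == prev_pos + 1:
                    run.append(r)
                else:
                    _flush_run(run, genome_id, genotype, sbs_rows, dbs_rows)
                    run = [r]
                prev_pos = r.pos
            _flush_run(run, genome_id, genotype, sbs_rows, dbs_rows)

    sbs = pd.DataFrame(sbs_rows, columns=["chrom", "pos", "ref", "alt", "genome", "genotype"])
    dbs = pd.DataFrame(dbs_rows, columns=["chrom", "pos", "ref", "alt", "genome", "genotype"])
    indels = pd.DataFrame(
        indel_rows, columns=["chrom", "pos", "length", "kind", "genome", "genotype"]
    )
    return MutationCatalog(sbs=sbs, dbs=dbs, indels=indels, n_source_records=len(records))


def _flush_run(run, genome_id, genotype, sbs_rows, dbs_rows) -> None:
    """Split a maximal adjacency run into DBS pairs left-to-right + SBS leftover."""
    i = 0
    while i + 1 < len(run):
        a, b = run[i], run[i + 1]
        dbs_rows.append(
            dict(chrom=a.chrom, pos=a.pos, ref=a.ref + b.ref, alt=a.alt + b.alt,
                 genome=genome_id, genotype=genotype)
        )
        i += 2
    if i < len(run):
        r = run[i]
        sbs_rows.append(
            dict(chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt,
                 genome=genome_id, genotype=genotype)
        )
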