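import numpy as np
import pandas as pd
import pytest

from formhaem.errors import InputError
from formhaem.io import write_vcf
from formhaem.variants import (
    FilterConfig,
    classify_variants,
    filter_variants,
    read_variants,
    records_from_frame,
)


def _records(rows):
    frame = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "depth", "af", "filter"]
    )
    return records_from_frame(frame, "g1", "WT")


# ---------------------------------------------------------------- I/O


def test_vcf_round_trip(tmp_path):
    frame = pd.DataFrame(
        [
            dict(chrom="chr1", pos=100, ref="C", alt="T", depth=40, af=0.5, filter="PASS"),
            dict(chrom="chr1", pos=250, ref="A", alt="G,T", depth=35, af=0.2, filter="PASS"),
            dict(
                chrom="chr2", pos=7, ref="T", alt="A", depth=10, af=0.1,
                filter="normal_artifact",
            ),
        ]
    )
    path = str(tmp_path / "g1.vcf")
    write_vcf(frame, path)
    records = read_variants({"g1": path}, {"g1": "WT"})
    assert len(records) == 4  # multiallelic row expands to two records
    assert records["multiallelic"].sum() == 2
    assert (records["genotype"] == "WT").all()
    flagged = records[records["filter"] != ""]
    assert flagged["filter"].tolist() == ["normal_artifact"]
    site = records[(records["chrom"] == "chr1") & (records["pos"] == 100)].iloc[0]
    assert (site["ref"], site["alt"], site["depth"]) == ("C", "T", 40)
    assert site["af"] == pytest.approx(0.5, abs=1e-4)


# ---------------------------------------------------------------- filtering


def test_filter_depth_and_vaf_boundaries_are_inclusive():
    records = _records(
        [
            ("chr1", 10, "C", "T", 20, 0.30, "PASS"),  # exactly on both bounds: keep
            ("chr1", 20, "C", "T", 19, 0.50, "PASS"),  # depth 19: reject
            ("chr1", 30, "C", "T", 50, 0.29, "PASS"),  # vaf 0.29: reject
        ]
    )
    kept, report = filter_variants(records, FilterConfig())
    assert kept["pos"].tolist() == [10]
    counts = dict(zip(report["reason"], report["count"]))
    assert counts == {"low_depth": 1, "low_vaf": 1}


def test_filter_rejects_flagged_and_multiallelic_first():
    records = _records(
        [
            ("chr1", 10, "C", "T", 5, 0.1, "normal_artifact"),  # flagged AND low depth
            ("chr1", 20, "A", "G,T", 5, 0.5, "PASS"),  # multiallelic AND low depth
            ("chr1", 30, "C", "T", 40, 0.5, "PASS"),
        ]
    )
    kept, report = filter_variants(records, FilterConfig())
    counts = dict(zip(report["reason"], report["count"]))
    assert counts == {"excluded_flag": 1, "multiallelic": 2}
    assert kept["pos"].tolist() == [30]


def test_filter_catches_all_planted_artifacts(mutation_batch):
    """Every artifact record is rejected and no true variant is lost."""
    records_by_genome, truth, _ = mutation_batch
    frames = [
        records_from_frame(frame, genome_id, genome_id.split("-")[0])
        for genome_id, frame in records_by_genome.items()
    ]
    records = pd.concat(frames, ignore_index=True)
    kept, report = filter_variants(records, FilterConfig())

    truth_counts = truth.variants.groupby("genome")["is_artifact"].agg(["sum", "count"])
    n_true = int((~truth.variants["is_artifact"]).sum())
    assert len(kept) == n_true
    # kept set matches the truth's non-artifact sites exactly
    true_sites = truth.variants.loc[
        ~truth.variants["is_artifact"], ["genome", "chrom", "pos"]
    ]
    kept_sites = kept[["genome", "chrom", "pos"]]
    merged = true_sites.merge(kept_sites, on=["genome", "chrom", "pos"], how="outer", indicator=True)
    assert (merged["_merge"] == "both").all()


def test_filter_empty_frame():
    kept, report = filter_variants(pd.DataFrame(columns=["chrom"]))
    assert kept.empty and report.empty


def test_filter_config_validation():
    with pytest.raises(InputError):
        FilterConfig(min_vaf=1.5)
    with pytest.raises(InputError):
        FilterConfig(min_depth=-1)


# ---------------------------------------------------------------- classification


def test_two_adjacent_snvs_merge_into_one_dbs():
    records = _records(
        [
            ("chr1", 100, "C", "T", 40, 0.5, "PASS"),
            ("chr1", 101, "T", "A", 40, 0.5, "PASS"),
        ]
    )
    catalog = classify_variants(records)
    assert len(catalog.dbs) == 1 and len(catalog.sbs) == 0
    row = catalog.dbs.iloc[0]
    assert (row["ref"], row["alt"], row["pos"]) == ("CT", "TA", 100)


def test_run_of_three_becomes_dbs_plus_sbs():
    records = _records(
        [
            ("chr1", 100, "C", "T", 40, 0.5, "PASS"),
            ("chr1", 101, "T", "A", 40, 0.5, "PASS"),
            ("chr1", 102, "G", "C", 40, 0.5, "PASS"),
        ]
    )
    catalog = classify_variants(records)
    assert len(catalog.dbs) == 1 and len(catalog.sbs) == 1
    assert catalog.dbs.iloc[0]["pos"] == 100
    assert catalog.sbs.iloc[0]["pos"] == 102


def test_adjacency_does_not_cross_chromosomes_or_genomes():
    a = _records([("chr1", 100, "C", "T", 40, 0.5, "PASS")])
    b = records_from_frame(
        pd.DataFrame(
            [dict(chrom="chr1", pos=101, ref="T", alt="A", depth=40, af=0.5, filter="PASS")]
        ),
        "g2",
        "WT",
    )
    catalog = classify_variants(pd.concat([a, b], ignore_index=True))
    assert len(catalog.sbs) == 2 and len(catalog.dbs) == 0

    c = _records(
        [
            ("chr1", 100, "C", "T", 40, 0.5, "PASS"),
            ("chr2", 101, "T", "A", 40, 0.5, "PASS"),
        ]
    )
    catalog = classify_variants(c)
    assert len(catalog.sbs) == 2 and len(catalog.dbs) == 0


def test_indel_lengths_are_net_allele_difference():
    records = _records(
        [
            ("chr1", 10, "A", "ATTT", 40, 0.5, "PASS"),  # +3 insertion
            ("chr1", 50, "ACGT", "A", 40, 0.5, "PASS"),  # -3 deletion
            ("chr1", 90, "ACG", "TGA", 40, 0.5, "PASS"),  # complex, net 0
            ("chr1", 120, "CA", "GT", 40, 0.5, "PASS"),  # explicit DBS allele
        ]
    )
    catalog = classify_variants(records)
    indels = catalog.indels.set_index("pos")
    assert indels.loc[10, "length"] == 3 and indels.loc[10, "kind"] == "insertion"
    assert indels.loc[50, "length"] == -3 and indels.loc[50, "kind"] == "deletion"
    assert indels.loc[90, "kind"] == "complex" and indels.loc[90, "length"] == 0
    assert len(catalog.dbs) == 1 and catalog.dbs.iloc[0]["pos"] == 120


def test_duplicate_positions_raise():
    records = _records(
        [
            ("chr1", 100, "C", "T", 40, 0.5, "PASS"),
            ("chr1", 100, "C", "A", 40, 0.5, "PASS"),
        ]
    )
    with pytest.raises(InputError):
        classify_variants(records)


def test_classification_conserves_filtered_records(mutation_batch):
    """#filtered records = #SBS + 2·#DBS + #indels for generator output."""
    records_by_genome, truth, _ = mutation_batch
    frames = [
        records_from_frame(frame, genome_id, genome_id.split("-")[0])
        for genome_id, frame in records_by_genome.items()
    ]
    kept, _ = filter_variants(pd.concat(frames, ignore_index=True))
    catalog = classify_variants(kept)
    assert len(kept) == len(catalog.sbs) + 2 * len(catalog.dbs) + len(catalog.indels)
    # and the per-genome counts match the planted truth
    truth_ok = truth.variants[~truth.variants["is_artifact"]]
    planted = truth_ok.groupby(["genome", "klass"]).size().unstack(fill_value=0)
    counts = catalog.counts_per_genome().set_index("genome")
    for genome_id in counts.index:
        assert counts.loc[genome_id, "sbs"] == planted.loc[genome_id].get("sbs", 0)
        assert counts.loc[genome_id, "dbs"] == planted.loc[genome_id].get("dbs", 0) // 2
        assert counts.loc[genome_id, "indel"] == planted.loc[genome_id].get("indel", 0)


def test_counts_per_genome_includes_genotype(mutation_batch):
    records_by_genome, _, _ = mutation_batch
    frames = [
        records_from_frame(frame, genome_id, genome_id.split("-")[0])
        for genome_id, frame in records_by_genome.items()
    ]
    kept, _ = filter_variants(pd.concat(frames, ignore_index=True))
    catalog = classify_variants(kept)
    counts = catalog.counts_per_genome()
    assert set(counts["genotype"]) == {"WT", "DKO"}
    assert len(counts) == 8
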