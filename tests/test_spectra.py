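import numpy as np
import pandas as pd
import pytest

from formhaem.contexts import CHANNELS_96, channel_of, revcomp
from formhaem.errors import InputError
from formhaem.io import Genome
from formhaem.spectra import (
    SbsProfile,
    aggregate_profiles,
    burden_table,
    cosine_rank,
    indel_size_distribution,
    relative_burden,
    sbs_context_profile,
    strand_bias,
)
from formhaem.variants import MutationCatalog, classify_variants, records_from_frame


def _sbs_frame(rows, genome_id="g1", genotype="WT"):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt"]
    ).assign(genome=genome_id, genotype=genotype)


def _catalog(sbs=None, dbs=None, indels=None):
    empty_sbs = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "genome", "genotype"])
    empty_indel = pd.DataFrame(columns=["chrom", "pos", "length", "kind", "genome", "genotype"])
    return MutationCatalog(
        sbs=sbs if sbs is not None else empty_sbs.copy(),
        dbs=dbs if dbs is not None else empty_sbs.copy(),
        indels=indels if indels is not None else empty_indel.copy(),
    )


# ---------------------------------------------------------------- channels


def test_channel_hand_examples():
    # C>T in ACA context stays on the pyrimidine strand
    assert channel_of("ACA", "T") == "A[C>T]A"
    # G>T in AGC context folds to the reverse complement: G[C>A]T
    assert channel_of("AGC", "T") == "G[C>A]T"


def test_channel_is_strand_symmetric():
    rng = np.random.default_rng(0)
    bases = "ACGT"
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for _ in range(200):
        triplet = "".join(rng.choice(list(bases), 3))
        alt = rng.choice([b for b in bases if b != triplet[1]])
        assert channel_of(triplet, alt) == channel_of(revcomp(triplet), complement[alt])


def test_profile_from_known_genome():
    genome = Genome({"chr1": "AACAG"})  # triplet at pos 3 (1-based) is ACA
    sbs = _sbs_frame([("chr1", 3, "C", "T"), ("chr1", 4, "A", "C")])
    profile = sbs_context_profile(sbs, genome)
    series = profile.to_series()
    assert series["A[C>T]A"] == 1
    # A>C at CAG folds to C[T>G]G
    assert series["C[T>G]G"] == 1
    assert profile.total == 2


def test_profile_reference_mismatch_raises():
    genome = Genome({"chr1": "AACAG"})
    sbs = _sbs_frame([("chr1", 3, "G", "T")])
    with pytest.raises(InputError):
        sbs_context_profile(sbs, genome)


def test_profile_skips_contig_edges():
    genome = Genome({"chr1": "ACGTA"})
    sbs = _sbs_frame([("chr1", 1, "A", "C"), ("chr1", 5, "A", "C"), ("chr1", 3, "G", "T")])
    profile = sbs_context_profile(sbs, genome)
    assert profile.total == 1


def test_profile_conserves_catalog_total(mutation_batch, small_genome):
    records_by_genome, _, _ = mutation_batch
    genome, _ = small_genome
    from formhaem.variants import FilterConfig, filter_variants

    frames = [
        records_from_frame(frame, gid, gid.split("-")[0])
        for gid, frame in records_by_genome.items()
    ]
    kept, _ = filter_variants(pd.concat(frames, ignore_index=True))
    catalog = classify_variants(kept)
    profile = sbs_context_profile(catalog, genome)
    assert profile.total == len(catalog.sbs)


# ---------------------------------------------------------------- aggregation


def test_aggregation_is_linear(rng):
    a = SbsProfile(rng.integers(0, 10, 96).astype(float))
    b = SbsProfile(rng.integers(0, 10, 96).astype(float))
    combined = aggregate_profiles([a, b])["all"]
    np.testing.assert_array_equal(combined.counts, a.counts + b.counts)
    grouped = aggregate_profiles([a, b], grouping=["x", "y"])
    np.testing.assert_array_equal(grouped["x"].counts, a.counts)
    normalized = aggregate_profiles([a, b], normalize=True)["all"]
    assert normalized.counts.sum() == pytest.approx(1.0)


def test_profile_validation():
    with pytest.raises(InputError):
        SbsProfile(np.zeros(95))
    with pytest.raises(InputError):
        SbsProfile(-np.ones(96))
    with pytest.raises(InputError):
        SbsProfile(np.zeros(96)).frequencies()


# ---------------------------------------------------------------- burden


def test_burden_table_mean_and_sem():
    sbs = pd.concat(
        [
            _sbs_frame([("chr1", p, "C", "T") for p in range(10, 10 + 4)], "g1", "WT"),
            _sbs_frame([("chr1", p, "C", "T") for p in range(100, 100 + 6)], "g2", "WT"),
        ],
        ignore_index=True,
    )
    per_genome, per_group = burden_table(_catalog(sbs=sbs))
    row = per_group[(per_group["genotype"] == "WT") & (per_group["kind"] == "sbs")].iloc[0]
    assert row["mean"] == 5.0
    # sample SD of {4, 6} is sqrt(2); SEM = sqrt(2)/sqrt(2) = 1
    assert row["sem"] == pytest.approx(1.0)


def test_burden_sem_is_null_for_single_genome():
    sbs = _sbs_frame([("chr1", 10, "C", "T")])
    _, per_group = burden_table(_catalog(sbs=sbs))
    assert per_group[per_group["kind"] == "sbs"]["sem"].isna().all()
    with pytest.raises(InputError):
        burden_table(_catalog())


# ---------------------------------------------------------------- relative burden


def test_relative_burden_reference_mean_is_one():
    sbs = pd.concat(
        [
            _sbs_frame([("chr1", p, "C", "T") for p in range(10, 14)], "w1", "WT"),
            _sbs_frame([("chr1", p, "C", "T") for p in range(50, 58)], "w2", "WT"),
            _sbs_frame([("chr1", p, "C", "T") for p in range(100, 118)], "d1", "DKO"),
        ],
        ignore_index=True,
    )
    table = relative_burden(_catalog(sbs=sbs), "WT").set_index("genome")
    # WT mean count is 6, so w1 -> 4/6, w2 -> 8/6, d1 -> 3
    assert table.loc["w1", "C>T"] == pytest.approx(4 / 6)
    assert table.loc["w2", "C>T"] == pytest.approx(8 / 6)
    assert table.loc["d1", "C>T"] == pytest.approx(3.0)
    wt_rows = table[table["genotype"] == "WT"]
    assert wt_rows["C>T"].mean() == pytest.approx(1.0)


def test_relative_burden_scales_linearly():
    sbs = pd.concat(
        [
            _sbs_frame([("chr1", p, "C", "T") for p in range(10, 15)], "w1", "WT"),
            _sbs_frame([("chr1", p, "C", "T") for p in range(100, 110)], "d1", "DKO"),
        ],
        ignore_index=True,
    )
    base = relative_burden(_catalog(sbs=sbs), "WT").set_index("genome")
    assert base.loc["d1", "C>T"] == pytest.approx(2.0)
    # doubling every genome leaves the relative burden unchanged
    doubled_rows = []
    for gid, genotype, lo, n in [("w1", "WT", 200, 10), ("d1", "DKO", 300, 20)]:
        doubled_rows.append(
            _sbs_frame([("chr1", p, "C", "T") for p in range(lo, lo + n)], gid, genotype)
        )
    doubled = relative_burden(
        _catalog(sbs=pd.concat(doubled_rows, ignore_index=True)), "WT"
    ).set_index("genome")
    assert doubled.loc["d1", "C>T"] == pytest.approx(2.0)


def test_relative_burden_zero_reference_type_is_null():
    sbs = pd.concat(
        [
            _sbs_frame([("chr1", 10, "C", "T")], "w1", "WT"),
            _sbs_frame([("chr1", 100, "T", "A")], "d1", "DKO"),
        ],
        ignore_index=True,
    )
    table = relative_burden(_catalog(sbs=sbs), "WT").set_index("genome")
    assert np.isnan(table.loc["d1", "T>A"])
    with pytest.raises(InputError):
        relative_burden(_catalog(sbs=sbs), "no-such-group")


# ---------------------------------------------------------------- cosine


def test_cosine_self_orthogonal_and_scale_invariance(signature_matrix):
    sig = signature_matrix.columns[0]
    vec = signature_matrix[sig].to_numpy()
    ranked = cosine_rank(SbsProfile(vec), signature_matrix)
    assert ranked.iloc[0]["signature"] == sig
    assert ranked.iloc[0]["cosine"] == pytest.approx(1.0)
    scaled = cosine_rank(SbsProfile(vec * 137.0), signature_matrix)
    pd.testing.assert_frame_equal(ranked, scaled)

    a = np.zeros(96)
    a[0] = 1.0
    b = pd.DataFrame({"other": np.zeros(96)}, index=list(CHANNELS_96))
    b.loc[CHANNELS_96[1], "other"] = 1.0
    assert cosine_rank(SbsProfile(a), b).iloc[0]["cosine"] == pytest.approx(0.0)


def test_cosine_recovers_generating_signature(signature_matrix, rng):
    """10,000 multinomial draws from each signature rank it first."""
    for sig in signature_matrix.columns:
        counts = rng.multinomial(10_000, signature_matrix[sig].to_numpy())
        ranked = cosine_rank(SbsProfile(counts.astype(float)), signature_matrix)
        assert ranked.iloc[0]["signature"] == sig


def test_cosine_rejects_zero_profile_and_bad_matrix(signature_matrix):
    with pytest.raises(InputError):
        cosine_rank(SbsProfile(np.zeros(96)), signature_matrix)
    with pytest.raises(InputError):
        cosine_rank(SbsProfile(np.ones(96)), signature_matrix.iloc[::-1])


# ---------------------------------------------------------------- strand bias


def test_strand_bias_toy_assignment():
    genome = Genome({"chr1": "A" * 50})
    genes = pd.DataFrame(
        [
            dict(chrom="chr1", start=0, end=10, name="gplus", strand="+"),
            dict(chrom="chr1", start=20, end=30, name="gminus", strand="-"),
        ]
    )
    sbs = _sbs_frame(
        [
            ("chr1", 5, "C", "T"),   # pyr on '+', inside '+' gene -> coding
            ("chr1", 6, "G", "A"),   # pyr on '-', inside '+' gene -> template
            ("chr1", 25, "C", "T"),  # pyr on '+', inside '-' gene -> template
            ("chr1", 26, "G", "A"),  # pyr on '-', inside '-' gene -> coding
            ("chr1", 45, "C", "T"),  # intergenic -> unassigned
        ]
    )
    table = strand_bias(sbs, genome, genes).set_index("type")
    assert table.loc["C>T", "coding"] == 2
    assert table.loc["C>T", "template"] == 2
    assert table.loc["C>T", "unassigned"] == 1
    assert table.loc["C>T", "ratio"] == pytest.approx(1.0)


def test_strand_bias_recovers_planted_odds(mutation_batch, small_genome):
    from formhaem.variants import filter_variants

    records_by_genome, _, scenario = mutation_batch
    genome, genes = small_genome
    frames = [
        records_from_frame(frame, gid, gid.split("-")[0])
        for gid, frame in records_by_genome.items()
    ]
    kept, _ = filter_variants(pd.concat(frames, ignore_index=True))
    catalog = classify_variants(kept)
    table = strand_bias(catalog, genome, genes).set_index("type")
    row = table.loc["T>A"]
    n = row["coding"] + row["template"]
    # planted odds 3: empirical ratio within a 3-sigma binomial envelope
    p = 3.0 / 4.0
    sd = np.sqrt(n * p * (1 - p))
    assert abs(row["coding"] - n * p) <= 3 * sd
    assert row["p_value"] < 0.05
    # an unbiased type shows no significant deviation at this sample size
    unbiased = table.loc["C>G"]
    m = unbiased["coding"] + unbiased["template"]
    assert abs(unbiased["coding"] - m / 2) <= 3 * np.sqrt(m * 0.25) + 1


# ---------------------------------------------------------------- indels


def test_indel_size_distribution_counts():
    indels = pd.DataFrame(
        [
            dict(chrom="chr1", pos=1, length=-2, kind="deletion", genome="g1", genotype="WT"),
            dict(chrom="chr1", pos=9, length=-2, kind="deletion", genome="g1", genotype="WT"),
            dict(chrom="chr1", pos=20, length=3, kind="insertion", genome="g1", genotype="WT"),
        ]
    )
    table = indel_size_distribution(_catalog(indels=indels))
    as_dict = {(r.genotype, r.length): r.count for r in table.itertuples()}
    assert as_dict == {("WT", -2): 2, ("WT", 3): 1}
    assert indel_size_distribution(_catalog()).empty
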