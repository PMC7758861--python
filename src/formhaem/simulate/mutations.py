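"""Per-genome somatic mutation catalogs drawn from signature mixtures.

Each simulated clone genome receives Poisson numbers of single-base
substitutions (channels drawn from a weighted mixture of 96-channel
signatures and placed at reference sites whose trinucleotide context
matches), tandem doublets (two adjacent substitutions), indels with
geometric sizes, and sub-threshold artifact records (low depth, low
allele fraction, or multiallelic) for the filtering stage to reject.
Transcriptional strand bias is planted by orienting the pyrimidine of
biased substitution types toward the coding or template strand of the
overlapping gene with configurable odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from formhaem.contexts import COMPLEMENT, PYRIMIDINES, split_channel
from formhaem.errors import ConfigurationError, GenerationError
from formhaem.io import Genome
from formhaem.truth import TruthBundle

_BASE2INT = {"A": 0, "C": 1, "G": 2, "T": 3}
_INT2BASE = "ACGT"


@dataclass
class ArtifactRates:
    """Expected artifact records per genome, by class."""

    sub_depth_rate: float = 0.0
    sub_vaf_rate: float = 0.0
    multiallelic_rate: float = 0.0


@dataclass
class MutScenario:
    """Study conditions for one whole-genome mutation-catalog batch."""

    sbs_mean: dict[str, float]
    dbs_mean: dict[str, float]
    indel_mean: dict[str, float]
    signature_weights: dict[str, float]
    n_genomes_per_genotype: dict[str, int]
    strand_bias_odds: dict[str, float] = field(default_factory=dict)
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    indel_geometric_p: float = 0.5
    max_indel_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name, means in (
            ("sbs_mean", self.sbs_mean),
            ("dbs_mean", self.dbs_mean),
            ("indel_mean", self.indel_mean),
        ):
            if any(v < 0 for v in means.values()):
                raise ConfigurationError(f"{name} values must be >= 0")
        total = sum(self.signature_weights.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigurationError(f"signature weights sum to {total}, not 1")
        if any(v <= 0 for v in self.strand_bias_odds.values()):
            raise ConfigurationError("strand bias odds must be > 0")

    @property
    def genotypes(self) -> list[str]:
        return list(self.n_genomes_per_genotype)


class _SiteIndex:
    """Per-context candidate sites of a genome, with strand orientation.

    For every position (excluding contig edges) the pyrimidine of the
    reference pair lies on either the forward or reverse strand; sites are
    bucketed by their pyrimidine-strand trinucleotide context. Orientation
    relative to overlapping genes: 1 = pyrimidine on the coding strand,
    2 = pyrimidine on the template (transcribed) strand, 0 = intergenic or
    ambiguous.
    """

    def __init__(self, genome: Genome, genes: pd.DataFrame):
        self.genome = genome
        self.chroms = genome.chromosomes
        self.sites: dict[str, dict[str, np.ndarray]] = {}

        strand_maps = {}
        for ci, chrom in enumerate(self.chroms):
            length = len(genome.sequences[chrom])
            smap = np.zeros(length, dtype=np.int8)  # 0 none, 1 plus, 2 minus, 3 both
            if genes is not None and len(genes):
                for row in genes[genes["chrom"] == chrom].itertuples():
                    code = 1 if row.strand == "+" else 2
                    seg = smap[row.start : row.end]
                    seg[seg == 0] = code
                    seg[(seg != 0) & (seg != code)] = 3
                    smap[row.start : row.end] = seg
            strand_maps[chrom] = smap

        buckets: dict[str, list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]] = {}
        for ci, chrom in enumerate(self.chroms):
            seq = np.frombuffer(genome.sequences[chrom].encode(), dtype=np.uint8)
            enc = np.full(seq.shape, -1, dtype=np.int8)
            for base, code in _BASE2INT.items():
                enc[seq == ord(base)] = code
            if len(enc) < 3:
                continue
            center = enc[1:-1]
            five = enc[:-2]
            three = enc[2:]
            pos = np.arange(1, len(enc) - 1)
            valid = (center >= 0) & (five >= 0) & (three >= 0)
            pyr_plus = (center == 1) | (center == 3)  # C or T on forward strand
            # pyrimidine-strand triplet: forward where center is C/T, else revcomp
            f5, fc, f3 = five.copy(), center.copy(), three.copy()
            rev = ~pyr_plus
            f5[rev] = 3 - three[rev]
            fc[rev] = 3 - center[rev]
            f3[rev] = 3 - five[rev]
            smap = strand_maps[chrom]
            gene_code = smap[1:-1]
            # orientation of the pyrimidine base relative to the gene
            pyr_code = np.where(pyr_plus, 1, 2)
            orient = np.zeros(len(pos), dtype=np.int8)
            genic = (gene_code == 1) | (gene_code == 2)
            orient[genic & (gene_code == pyr_code)] = 1  # coding
            orient[genic & (gene_code != pyr_code)] = 2  # template
            key = f5 * 16 + fc * 4 + f3
            for ctx_code in np.unique(key[valid]):
                mask = valid & (key == ctx_code)
                ctx = (
                    _INT2BASE[ctx_code // 16]
                    + _INT2BASE[(ctx_code // 4) % 4]
                    + _INT2BASE[ctx_code % 4]
                )
                buckets.setdefault(ctx, []).append(
                    (
                        np.full(mask.sum(), ci, dtype=np.int32),
                        pos[mask].astype(np.int64),
                        pyr_plus[mask],
                        orient[mask],
                    )
                )
        for ctx, parts in buckets.items():
            self.sites[ctx] = {
                "chrom": np.concatenate([p[0] for p in parts]),
                "pos": np.concatenate([p[1] for p in parts]),
                "pyr_plus": np.concatenate([p[2] for p in parts]),
                "orient": np.concatenate([p[3] for p in parts]),
            }

    def candidates(self, context: str) -> dict[str, np.ndarray]:
        if context not in self.sites:
            raise GenerationError(f"no reference site matches context {context}")
        return self.sites[context]


def _draw_site(
    index: _SiteIndex,
    context: str,
    odds: float | None,
    blocked: set[tuple[int, int]],
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[int, int, bool, int]:
    """Pick an unblocked candidate site, honouring strand-orientation odds."""
    cand = index.candidates(context)
    n = len(cand["pos"])
    pool = None
    if odds is not None and odds != 1.0:
        genic = cand["orient"] > 0
        n_genic = int(genic.sum())
        if n_genic and rng.random() < n_genic / n:
            want = 1 if rng.random() < odds / (1.0 + odds) else 2
            sel = np.where(cand["orient"] == want)[0]
            if len(sel):
                pool = sel
        if pool is None:
            pool = np.where(cand["orient"] == 0)[0]
            if not len(pool):
                pool = None
    for _ in range(max_tries):
        j = int(rng.choice(pool)) if pool is not None else int(rng.integers(n))
        key = (int(cand["chrom"][j]), int(cand["pos"][j]))
        if key in blocked:
            continue
        return key[0], key[1], bool(cand["pyr_plus"][j]), int(cand["orient"][j])
    raise GenerationError(f"could not place a mutation in context {context}")


def _block(blocked: set[tuple[int, int]], chrom: int, start: int, end: int) -> None:
    for p in range(start, end + 1):
        blocked.add((chrom, p))


def generate_mutation_catalogs(
    scenario: MutScenario,
    genome: Genome,
    genes: pd.DataFrame,
    signatures: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], TruthBundle]:
    """Generate per-clone VCF-style variant tables plus planted truth.

    Returns ``(records, truth)`` where ``records`` maps genome id to a
    DataFrame with columns ``chrom, pos, ref, alt, depth, af, filter``
    (``pos`` 1-based; multiallelic artifact rows carry comma-joined ALT/AF)
    and ``truth.variants`` records every planted event with its class,
    signature of origin, channel, and strand orientation.
    """
    for sig_id in scenario.signature_weights:
        if sig_id not in signatures.columns:
            raise ConfigurationError(f"signature {sig_id!r} not in the signature matrix")

    rng = np.random.default_rng(scenario.seed)
    index = _SiteIndex(genome, genes)
    chrom_names = genome.chromosomes
    chrom_lengths = np.array([len(genome.sequences[c]) for c in chrom_names])

    sig_ids = list(scenario.signature_weights)
    sig_probs = np.array([scenario.signature_weights[s] for s in sig_ids])
    sig_cols = {s: signatures[s].to_numpy() for s in sig_ids}
    channels = list(signatures.index)

    records: dict[str, pd.DataFrame] = {}
    truth_rows: list[dict] = []

    def passing_depth_af() -> tuple[int, float]:
        depth = int(rng.integers(20, 61))
        af = float(np.clip(rng.normal(0.5, 0.05), 0.30, 0.95))
        return depth, af

    def type_odds(ref: str, alt: str) -> float | None:
        return scenario.strand_bias_odds.get(f"{ref}>{alt}")

    dbs_counter = 0
    for genotype, n_genomes in scenario.n_genomes_per_genotype.items():
        for g in range(n_genomes):
            genome_id = f"{genotype}-g{g + 1}"
            blocked: set[tuple[int, int]] = set()
            rows: list[dict] = []

            def emit(chrom_i, pos0, ref, alt, depth, af, filt, **truth):
                rows.append(
                    dict(
                        chrom=chrom_names[chrom_i],
                        pos=pos0 + 1,
                        ref=ref,
                        alt=alt,
                        depth=depth,
                        af=af,
                        filter=filt,
                    )
                )
                entry = dict(
                    genome=genome_id,
                    genotype=genotype,
                    chrom=chrom_names[chrom_i],
                    pos=pos0 + 1,
                    ref=ref,
                    alt=alt,
                    is_artifact=False,
                    signature=None,
                    channel=None,
                    strand_category=None,
                    artifact_reason=None,
                    dbs_id=None,
                )
                entry.update(truth)
                truth_rows.append(entry)

            # --- single-base substitutions from the signature mixture
            n_sbs = rng.poisson(scenario.sbs_mean.get(genotype, 0.0))
            for _ in range(n_sbs):
                sig = sig_ids[int(rng.choice(len(sig_ids), p=sig_probs))]
                channel = channels[int(rng.choice(96, p=sig_cols[sig]))]
                five, p_ref, p_alt, three = split_channel(channel)
                context = five + p_ref + three
                odds = type_odds(p_ref, p_alt)
                ci, pos, pyr_plus, orient = _draw_site(index, context, odds, blocked, rng)
                if pyr_plus:
                    ref, alt = p_ref, p_alt
                else:
                    ref, alt = COMPLEMENT[p_ref], COMPLEMENT[p_alt]
                depth, af = passing_depth_af()
                cat = {0: "unassigned", 1: "coding", 2: "template"}[orient]
                emit(
                    ci, pos, ref, alt, depth, af, "PASS",
                    klass="sbs", signature=sig, channel=channel, strand_category=cat,
                )
                _block(blocked, ci, pos - 1, pos + 1)

            # --- tandem doublets: two adjacent substitutions
            n_dbs = rng.poisson(scenario.dbs_mean.get(genotype, 0.0))
            for _ in range(n_dbs):
                for _try in range(200):
                    ci = int(rng.choice(len(chrom_names), p=chrom_lengths / chrom_lengths.sum()))
                    pos = int(rng.integers(1, chrom_lengths[ci] - 2))
                    if all((ci, p) not in blocked for p in range(pos - 1, pos + 3)):
                        break
                else:
                    raise GenerationError("could not place a DBS")
                dbs_counter += 1
                seq = genome.sequences[chrom_names[ci]]
                for off in (0, 1):
                    ref = seq[pos + off]
                    alt = rng.choice([b for b in "ACGT" if b != ref])
                    depth, af = passing_depth_af()
                    emit(
                        ci, pos + off, ref, str(alt), depth, af, "PASS",
                        klass="dbs", dbs_id=dbs_counter,
                    )
                _block(blocked, ci, pos - 1, pos + 2)

            # --- indels with geometric sizes
            n_indel = rng.poisson(scenario.indel_mean.get(genotype, 0.0))
            for _ in range(n_indel):
                size = min(int(rng.geometric(scenario.indel_geometric_p)), scenario.max_indel_size)
                is_ins = rng.random() < 0.5
                span = 1 if is_ins else size + 1
                for _try in range(200):
                    ci = int(rng.choice(len(chrom_names), p=chrom_lengths / chrom_lengths.sum()))
                    pos = int(rng.integers(1, chrom_lengths[ci] - span - 1))
                    if all((ci, p) not in blocked for p in range(pos - 1, pos + span + 1)):
                        break
                else:
                    raise GenerationError("could not place an indel")
                seq = genome.sequences[chrom_names[ci]]
                if is_ins:
                    ref = seq[pos]
                    alt = ref + "".join(rng.choice(list("ACGT"), size=size))
                else:
                    ref = seq[pos : pos + size + 1]
                    alt = seq[pos]
                depth, af = passing_depth_af()
                emit(ci, pos, ref, alt, depth, af, "PASS", klass="indel")
                _block(blocked, ci, pos - 1, pos + span)

            # --- sub-threshold artifact records (true negatives for the filter)
            def artifact_site(span: int = 1) -> tuple[int, int]:
                for _try in range(200):
                    ci = int(rng.choice(len(chrom_names), p=chrom_lengths / chrom_lengths.sum()))
                    pos = int(rng.integers(1, chrom_lengths[ci] - span - 1))
                    if all((ci, p) not in blocked for p in range(pos - 1, pos + span)):
                        return ci, pos
                raise GenerationError("could not place an artifact")

            def random_snv(ci: int, pos: int) -> tuple[str, str]:
                ref = genome.sequences[chrom_names[ci]][pos]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                return ref, alt

            for reason, rate in (
                ("low_depth", scenario.artifact_rates.sub_depth_rate),
                ("low_vaf", scenario.artifact_rates.sub_vaf_rate),
                ("multiallelic", scenario.artifact_rates.multiallelic_rate),
            ):
                for _ in range(rng.poisson(rate)):
                    ci, pos = artifact_site()
                    ref, alt = random_snv(ci, pos)
                    if reason == "low_depth":
                        depth = int(rng.integers(5, 20))
                        af = float(np.clip(rng.normal(0.5, 0.05), 0.30, 0.95))
                        filt = "PASS"
                    elif reason == "low_vaf":
                        depth, _ = passing_depth_af()
                        af = float(rng.uniform(0.05, 0.29))
                        filt = "normal_artifact" if rng.random() < 0.5 else "PASS"
                    else:  # multiallelic
                        alt2 = str(rng.choice([b for b in "ACGT" if b not in (ref, alt)]))
                        alt = f"{alt},{alt2}"
                        depth, af = passing_depth_af()
                        filt = "PASS"
                    rows.append(
                        dict(
                            chrom=chrom_names[ci], pos=pos + 1, ref=ref, alt=alt,
                            depth=depth, af=af, filter=filt,
                        )
                    )
                    truth_rows.append(
                        dict(
                            genome=genome_id, genotype=genotype,
                            chrom=chrom_names[ci], pos=pos + 1, ref=ref, alt=alt,
                            klass="artifact", is_artifact=True, signature=None,
                            channel=None, strand_category=None,
                            artifact_reason=reason, dbs_id=None,
                        )
                    )
                    _block(blocked, ci, pos - 1, pos + 1)

            columns = ["chrom", "pos", "ref", "alt", "depth", "af", "filter"]
            records[genome_id] = (
                pd.DataFrame(rows, columns=columns)
                .sort_values(["chrom", "pos"])
                .reset_index(drop=True)
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "genome", "genotype", "chrom", "pos", "ref", "alt", "klass",
            "is_artifact", "signature", "channel", "strand_category",
            "artifact_reason", "dbs_id",
        ],
    )
    return records, TruthBundle(variants=truth)
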