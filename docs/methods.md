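# Methods

Models, parameter defaults, and design rationale for each module. All
defaults are the documented study conditions of the analyses the package
reimplements; none are fitted to outputs.

## Synthetic data generators (`formhaem.simulate`)

### scRNA-seq (`generate_scrna`)

Counts are negative-binomial per gene with population-specific means.
Each population has a relative expression program over non-mitochondrial
genes: a shared log-normal(0, 1.5) baseline with that population's marker
genes multiplied by `2**marker_log_fc` (log2 fold-change, default 2.0),
renormalized to sum to 1. Programs are drawn from a genotype-independent
RNG stream — cell identity is shared biology; genotypes differ only in
composition and sampling noise. Per-cell library sizes are
log-normal(8.5, 0.35) (≈ 4,900 UMIs median); a per-cell mitochondrial
fraction N(0.05, 0.02) clipped to [0, 0.95] routes counts to the 10
`mt-`-prefixed genes. NB dispersion (size) defaults to 2.0.

Planted artifacts:
- **Doublets** (`doublet_fraction`): element-wise sums of two freshly drawn
  singlet profiles — a droplet with two cells holds both cells' molecules.
- **Low-quality cells** (`lowquality_fraction`): mito fraction pinned to
  0.30, expressed repertoire restricted to 300 random non-mito genes,
  library halved — each violating a QC rule by construction.

Reproducibility: per-genotype streams derive from
`SeedSequence([seed, crc32(tag)])`, so runs are bit-identical and adding a
genotype does not perturb the others.

### Genomes and mutation catalogs (`generate_genome`, `generate_mutation_catalogs`)

Genomes are uniform-random sequences (defaults: 2 chromosomes, configurable
length) with non-overlapping stranded genes covering `gene_density` of each
chromosome (exponential gene lengths, mean 5 kb). Uniform composition makes
each of the 64 trinucleotide contexts equally available, so planted channel
frequencies converge to the signature mixture.

Per genome, event counts are Poisson at per-genotype means. SBS channels are
drawn from the weighted signature mixture and placed on sites whose
pyrimidine-strand context matches; sites are blocked ±1 bp around existing
substitutions so no spurious adjacency (and hence no accidental DBS) is
created. DBS events are placed as two adjacent substitutions sharing an id.
Indel lengths are geometric (p = 0.5) capped at 20 bp. Strand bias: for a
substitution type with odds ω, genic placements put the pyrimidine on the
coding strand with probability ω/(1+ω); genic-vs-intergenic proportions
follow site availability.

Artifacts (per-genome expected counts, Poisson): low-depth records
(depth 5–19), low-VAF records (0.05–0.29; flagged `normal_artifact` with
probability 0.5), and multiallelic sites. Passing records draw depth
uniform 20–60 and VAF N(0.5, 0.05) clipped to [0.3, 0.95].

### Chemistry (`generate_gcms_batch`, `generate_absorbance_trace`)

Area ratios sit on a true line `ratio = slope·conc + intercept`
(defaults 2.0, 0.05) perturbed by unit-mean multiplicative log-normal noise
with the configured CV (σ² = ln(1 + CV²)). Group concentrations are planted
in µM and converted with the formaldehyde molar mass 30.026 g/mol.
Absorbance traces are two linear segments (baseline, then reaction after
substrate addition at 300 s) plus optional Gaussian noise.

## Single-cell QC (`formhaem.qc`)

Stage order: doublet removal → threshold rules → normalization.

- **Doublet scoring**: synthetic doublets are sums of uniformly sampled
  distinct cell pairs, 25% of n. Observed + synthetic cells are total-count
  normalized (median target), log1p transformed, reduced to 50 PCs
  (randomized SVD, seeded); a cell's score is the fraction of its k = 30
  Euclidean nearest neighbours (excluding itself) that are synthetic.
  The top ⌈0.045·n⌉ scores per sample are removed; ties break by
  descending score then ascending cell id for reproducibility.
- **Rules** (strict inequalities): mito fraction > 0.10; expressed genes
  < 1,200; |total − per-sample mean| > 3 per-sample SD. Means/SDs are
  computed on the post-doublet-removal cells, per sample.
- **Normalization**: each cell scaled to the median total (raw counts kept
  in `layers["counts"]`; zero-total cells dropped with a warning).

## Clustering and annotation (`formhaem.cluster`)

log1p of the normalized matrix, restricted to 2,000 highly variable genes
(Seurat flavor), 50 PCs (randomized SVD, seeded), symmetrized k = 15 NN
graph, Louvain community detection (igraph multilevel with resolution
parameter; igraph's RNG seeded for determinism). Labels are relabelled
0..K−1 by decreasing size. The subclustering default resolution is 0.6 — a
tuned default recorded as such, since the upstream description leaves the
resolution unstated while fixing the expected cluster count.

Annotation replaces a manual step: per cluster and population, the score is
the mean over the population's markers of cluster-mean expression scaled to
[0, 1] across clusters (constant genes scale to 0); a cluster takes the
argmax population if its score ≥ 0.5, else stays `unassigned`.

Label transfer fits HVG selection and PCA on the reference only, projects
query cells, and takes the majority label among k nearest reference cells
(ties → single nearest neighbour). Occupancy reports count/total/fraction
of a focus identity per genotype.

Marker ranking: Wilcoxon rank-sum (one cluster vs rest) on log1p data with
Benjamini–Hochberg correction; reported genes have adjusted p < 0.05 and
log2 fold-change > 0.25; singleton clusters are excluded with a warning.

## Gene-program scores (`formhaem.scores`)

- `module_score`: `(1/n)·Σ_g ln(x_g+1)` over the geneset's genes, with
  `x_g` total-count-normalized (not logged) expression and n the full
  geneset size; absent genes contribute 0 and are logged.
- `cell_cycle_assign`: S and G2/M program scores against 50 control genes
  per program gene drawn (seeded) from 25 expression-matched bins; phase is
  the argmax of (S, G2M) when positive, else G1. Null data therefore calls
  ≈ half the cells S/G2M with near-zero scores — a property of the rule.
- `dna_repair_deg_summary`: per (genotype, cluster), the count and median
  log2 fold-change of differentially expressed genes intersecting a repair
  geneset.

## Variants and spectra (`formhaem.variants`, `formhaem.spectra`)

Filtering keeps records with depth ≥ 20 and VAF ≥ 0.3 (both inclusive),
no excluded FILTER flag (default `normal_artifact`), and no multiallelic
site. Rejections are reported by the first matching rule in the order:
multiallelic → excluded flag → low depth → low VAF → unusable.

Classification merges maximal runs of adjacent same-genome SNVs into DBS
pairs left-to-right (trailing singleton stays SBS), so
`#records = #SBS + 2·#DBS + #indels`. Explicit length-2 equal-length
alleles are DBS; length-changing alleles are indels of the net length;
longer equal-length alleles are "complex" (length 0). Overlapping records
at one position are an input error.

Profiles use the pyrimidine convention: channel order is substitution type
(C>A, C>G, C>T, T>A, T>C, T>G) × 5′ flank × 3′ flank, flanks alphabetical;
purine-reference sites are reverse-complemented with their context.
Burden tables report per-group mean ± SEM (SD/√n, ddof = 1; SEM null for
n = 1). Relative burden divides per-genome type counts by the
reference-group mean (zero reference means → null with a warning).
Cosine ranking is scale-invariant by construction. Strand bias assigns
genic substitutions by pyrimidine-on-coding vs pyrimidine-on-template and
tests against 0.5 with a two-sided exact binomial.

The bundled `synthetic_signatures()` are five deterministic, mutually
well-separated synthetic shapes — a stand-in collection, not copies of any
published catalog (reference catalogs are pluggable via `load_signatures`).

## Chemistry (`formhaem.chem`)

Calibration is unweighted OLS of area ratio on nominal concentration
(`scipy.stats.linregress`), with per-level replicate CVs (ddof = 1) and a
15% precision bound. Quantification inverts the line and converts
mg/l → µM via 1000/30.026; an `in_range` flag marks extrapolation.
Fold changes are group means over the reference-group mean.

Enzyme activity fits least-squares slopes before and after substrate
addition; the net ΔA/min converts via Beer–Lambert with
ε = 6220 l·mol⁻¹·cm⁻¹ (NADH, 340 nm) and a 1 cm path, reported per mg
protein (µM·min⁻¹·mg⁻¹ by default, or mol·min⁻¹·mg⁻¹ using the reaction
volume). `extinction_coefficient` inverts A = ε·c·L from a mass
concentration and molar mass.

A note on ratio estimation: when a group's concentration sits near the
bottom of the calibration range, the per-batch fold change
(mean_A/mean_B) is convexity-biased and heavy-tailed across batches; the
reproduction script therefore aggregates across seeds as the ratio of
pooled group means, which matches the "ratio of estimated group means"
definition and is the standard ratio estimator.

## Pipeline and configuration

`PipelineConfig` (pydantic, `extra="forbid"`) validates every block
together and fills the documented defaults; `normalize` is idempotent.
Stages: `simulate`, `sc-qc`, `sc-cluster`, `sc-score`, `mutsig`, `chem`.
The simulate stage writes real interchange formats (MTX + TSVs, FASTA,
BED6, VCF v4.2 with DP/AF in INFO, CSV), and the analysis stages read them
back through the same readers a real dataset would use. Every run writes a
`manifest.json` with the config snapshot, seed, input checksums, and
per-stage record counts.

## Scope and limitations

- Generators model the statistical structure the analyses assume, not
  mechanistic biology: NB expression with program means, Poisson burdens,
  log-normal analytical noise.
- Alignment and variant calling are out of scope; the variant arm consumes
  caller-style output.
- UMAP layout, trajectory inference and batch integration beyond PCA-space
  kNN transfer are out of scope.
- Cluster counts at a given Louvain resolution are data- and
  resolution-dependent; the 0.6 subclustering default is a recorded tuned
  default, not a derivation.
- The cell-cycle G1 assignment is a thresholded argmax; on program-free
  data phase calls are near-coin-flip with near-zero scores.
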