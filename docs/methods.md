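# Methods

This note documents the models, conventions and design choices behind
pairclone, in the order the pipeline runs them.

## Cohort model and I/O

A cohort is a set of patients, each contributing one primary-tumor sample
and one matched lymph-node-metastasis sample; an unpaired validation cohort
is a set of site-labelled samples. Mutations are identified within a patient
by `(chrom, pos, ref, alt)` with 1-based inclusive coordinates (MAF
convention); duplicate records of one mutation within one sample are
collapsed with a warning. Tumor purity is a sample-sheet column; when
absent it defaults to 1.0 with a logged warning, which makes CCF equal the
copy-number-corrected VAF scale and is the right degenerate behavior for
cohorts reported without purity estimates. Variant classes are mapped from
MAF `Variant_Classification` strings by a fixed table; anything unknown maps
to `other`. Synonymous and `other` calls are retained in all tables but are
not eligible for TMB or the driver screen.

## CCF estimation and clonality

The estimator is the standard purity/ploidy-corrected point estimate.
With purity *p*, tumor local total copy number *c* (record field, default 2
= heterozygous diploid) and multiplicity *m*:

    CCF = VAF · (p·c + (1−p)·2) / (p·m),   m = max(1, round(VAF·(p·c+(1−p)·2)/p))

clamped to [0, 1]. No posterior or confidence interval is computed: the
downstream consumer is a binary clonal/subclonal call at a fixed threshold,
**clonal iff CCF > 0.6** (strict; CCF = 0.6 is subclonal). Assumptions worth
stating:

- The diploid default is an assumption, not an inference; cohorts without
  copy-number calls are treated as CN-neutral. The `total_cn` field
  overrides it per record when available.
- Integer multiplicity estimation makes the CCF **piecewise** monotone in
  VAF: at the VAF where the `m` estimate steps from 1 to 2 the CCF halves.
  Monotonicity holds exactly at fixed multiplicity; tests assert exactly
  that.
- Purity enters both the correction and the multiplicity estimate, so very
  low purity with moderate depth inflates label noise near the threshold;
  the recovery property below quantifies the regime where labels are
  trustworthy.

## Concordance

Per pair, mutation keys are partitioned into shared (both samples) and
private (one sample). Concordance is |shared| / |union| — the Jaccard index
— reported as a percentage with one decimal. This shared-fraction
definition is the one consistent with per-patient percentages; a per-gene
binary-profile Pearson correlation is offered as a clearly separate
secondary metric (`gene_profile_correlation`), not mixed into the summary.
The cohort summary uses the sample SD (n−1); a single-pair cohort reports
SD 0 with an explicit `sd_defined = 0` flag. Pairs with an empty mutation
union are excluded with a warning.

## Tumor mutational burden

TMB = eligible mutations / panel megabases. Eligible classes default to the
nonsilent coding set (missense, nonsense, splice, frameshift and in-frame
indels); the footprint defaults to 1.94 Mb, a typical TMB-callable region
for a large targeted oncology assay. Both are conventions surfaced as
parameters, since assay-specific protocols differ. Group comparisons
(site, smoking) use the two-sided Wilcoxon rank-sum (Mann–Whitney U) test,
exact for small tie-free groups.

## Mutational signatures

SNVs are strand-normalized to a pyrimidine reference, giving 96 classes
(6 substitution types × 16 flanking contexts) in the canonical catalog row
order. The 96 × samples count matrix is decomposed by NMF with the
Frobenius objective and multiplicative updates (scikit-learn's `mu`
solver), max 200 iterations, tolerance 1e-6, best of 20 random restarts
derived deterministically from a seed (default 17); signature columns are
normalized to sum 1 with scale absorbed into contributions. k = 2 by
default. De novo signatures are mapped to the packaged catalog by **Pearson
correlation** (cosine is easy to compute alongside but Pearson is the
primary metric); ties break toward the lower catalog index with a warning,
and constant vectors are excluded as unmatchable. Samples are grouped by
agglomerative clustering (Euclidean distance on contribution proportions,
complete linkage, cut at 2); the cluster loading higher on the signature
mapped to the lowest catalog id is labelled S1. NMF is run jointly on all
samples of the cohort (both sites), so paired samples can land in the same
or different clusters — itself an observable of interest.

### Packaged reference catalog

The true COSMIC v2 matrix is not redistributable here, so the package ships
a clearly labelled **synthetic stand-in** (`cosmic_v2_synthetic.tsv`): 30
seeded, mutually distinct profiles (pairwise Pearson r < 0.5), in which
profile 1 carries the CpG-deamination character (C>T at NpCpG) of the real
signature 1 and profile 23 is C>T-leaning with an elevated T>A component.
The simulator draws contexts from this same catalog, so identity mapping of
de novo signatures is exercised exactly as it would be with the real
catalog; correlations against the *real* COSMIC v2 will of course differ.

## Driver screen

Candidate metastasis-related events per pair are (i) **LN-private**
mutations — key absent from the matched primary's record set; no VAF-noise
rescue is attempted, though a minimum-depth presence check can be layered on
by the caller — and (ii) **subclonal→clonal shifts** — shared mutations
subclonal in the primary and clonal in the node. Shared-and-clonal-in-both
mutations never qualify. The gene-function step is a configurable allowlist
(one symbol per line) standing in for manual curation; an empty allowlist
is an error because it would nullify the screen.

Validation uses sample-level 2×2 tables per gene in an unpaired cohort:
LN samples mutated/not vs primary samples mutated/not, counting only
nonsilent mutations. The test is the in-package Fisher exact test,
**one-sided with alternative "greater prevalence in LN"**, matching the
directional hypothesis that metastasis-promoting alterations are enriched
in metastases. The decision flag is raw p ≤ 0.05; Benjamini–Hochberg
q-values are computed across the tested genes and reported alongside, but
do not drive the flag. Odds ratios use the Haldane 0.5 correction when any
cell is zero. The Fisher implementation evaluates small tables (N ≤ 200)
in exact integer arithmetic and larger ones via log-gamma; two-sided
p-values use the point-probability rule.

## Synthetic cohort generator

The generator encodes a two-site **linear-progression** seeding model: the
node's founding lineage branches late from the primary's dominant clone.

Per patient: truncal count ~ Poisson(λ_T·G) with patient factor
G ~ Gamma(shape k, mean 1) — the gamma mixing makes the truncal *fraction*
vary between patients, which is what spreads per-pair concordance over
nearly [0, 1] as seen in real pairs; primary-private count ~ Poisson(λ_P),
LN-private ~ Poisson(λ_L); a Binomial(shift_fraction) subset of the
primary-private mutations is shared and clonal in the node. True CCFs:
truncal 1.0 in both; primary-private uniform on (0, 0.6]; LN-private and
shifted-in-LN uniform on (0.6, 1]. Observed counts: depth ~
Poisson(mean_depth) truncated at ≥ 10 reads; alt ~ Binomial(depth,
purity·CCF/2) under the heterozygous diploid model (the CN column is left
empty by default — the analysis target has no copy-number component).
Trinucleotide contexts are drawn per mutation from the sample's signature
mixture over the packaged catalog; mixtures alternate between patients
(defaults 85/15 and 15/85 over profiles 1 and 23, Dirichlet-jittered per
sample), producing two recoverable contribution clusters. Patient metadata
(age, sex, stage, smoking) are drawn from rates typical of an advanced
NSCLC surgical cohort. Each configured driver gene is planted as an
LN-private mutation in `n_driver_carriers` random patients so the screen's
candidate stage can see it.

**Default calibration.** λ_T = 7, λ_P = 4.5, λ_L = 1.5, shift_fraction =
0.1, k = 0.5, purity ~ U(0.4, 0.9), mean depth 800. These were fixed once,
via the closed-form concordance expectation (below), to reproduce a
per-pair concordance distribution with mean ≈ 42%, SD ≈ 29% and per-sample
mutation loads near medians of 11 (primary) and 8 (node) — the regime of
interest for paired nodal cohorts. They are a calibration of the
generator, not measurements.

`expected_concordance` integrates E[(t + f·p)/(t + p + l)] over the exact
count distributions (negative binomial × Poisson × Poisson, conditioned on
a non-empty union), with the shifted count entering through its conditional
mean and variance. It is an independent analytic route against which the
simulation's empirical mean is tested.

The validation-cohort generator mutates each panel gene per sample as an
independent Bernoulli: baseline rate in primaries; in LN samples the rate
implied by the gene's configured odds ratio (odds_LN = OR·q/(1−q)), or
both rates set directly per gene for prevalence emulation. One
nonsilent SNV record is emitted per mutated (sample, gene) at a
gene-specific locus — gene-level presence is the only quantity the
enrichment stage consumes.

**What the generator does not emulate:** multi-region sampling, subclonal
phylogenies deeper than the two-site linear model, parallel progression,
copy-number alterations, sequencing artifacts, germline contamination, and
mutational hotspots (loci are uniform). Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to real-data pathologies outside it.

## Problem sizes and numerical checks

Test and acceptance workloads are sized to run comfortably on one CPU:
clonality recovery on 200 pairs at mean depth 800 and purity ≥ 0.6
(label-recovery requirement: ≥ 95%); signature recovery on 50 samples of
~200 SNVs (cosine ≥ 0.95 to the generating profiles, correct catalog ids);
driver-screen power over 25 seeds of 15 pairs + 2000/2000 validation
samples with OR = 4 drivers at 3% baseline (≥ 80% power, null flag rate
near the nominal 5%); Fisher exactness over all ~2.5×10⁵ tables with row
margins ≤ 30 (agreement to 1e-12 with rational-arithmetic enumeration).
The prevalence-emulation check uses 800 primary / 600 LN samples, a
plausible split for a large unpaired lung cohort with site labels, at which
the power to flag a 2%→5% difference is ≈ 94% and 3%→8% is > 99%.

## Known limitations

- The CCF estimator is a point estimate; near-threshold mutations at
  moderate depth carry label noise that no amount of cohort size removes.
- Concordance treats mutation calling as perfect; in real data, private
  calls can be coverage artifacts of the other sample. A minimum-depth
  presence check is the natural extension point.
- The packaged signature catalog is synthetic; analyses of real cohorts
  should substitute the real COSMIC matrix (same TSV shape) before
  interpreting catalog ids biologically.
- TMB values depend linearly on the assumed panel footprint; cross-study
  comparison requires matching footprints and eligibility conventions.
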