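# Methods

This note documents the models and procedures implemented in `tandem5hmc`,
the assumptions behind them, the defaults of the synthetic-data generator,
and the numerical choices that matter when reproducing or extending the
analyses.

## Measurement model and deconvolution

Tandem treatment of each DNA aliquot yields two Infinium beta values per
CpG: the bisulfite (BS) beta reads the sum of methylation marks,
E[βBS] = p5mC + p5hmC, while the oxidative-bisulfite (OxBS) beta reads
methylation alone, E[βOxBS] = p5mC. The unmethylated fraction is the
simplex remainder pC = 1 − p5mC − p5hmC.

Two estimators invert this model per cell:

- **Constrained subtraction** (`deconvolve_naive`):
  p̂5hmC = max(βBS − βOxBS, 0), p̂5mC = min(βOxBS, βBS). The truncation at
  zero and the cap at βBS guarantee a valid simplex; the cost is a point
  mass at zero wherever the true 5hmC signal is below the noise floor.
- **Maximum likelihood** (`deconvolve_ml`): βBS ~ Beta(μ1 φ, (1−μ1) φ) with
  μ1 = p5mC + p5hmC, βOxBS ~ Beta(μ2 φ, (1−μ2) φ) with μ2 = p5mC, and a
  shared precision φ. The joint likelihood is maximised over the simplex
  per cell (coarse 0.05-step simplex scan to pick the basin, then SLSQP;
  means are clamped to [1e-6, 1−1e-6]). In the φ → ∞ limit it agrees with
  the subtraction estimator on consistent inputs, and it pools the two
  treatments when they are inconsistent (βBS < βOxBS) instead of
  truncating. φ is a single shared nuisance parameter: with one observation
  per treatment per cell, per-locus precisions are not identifiable. The ML
  path solves one small optimisation per cell and is intended for locus
  panels, not full arrays.

Loci with any missing beta in either treatment are dropped at ingest with a
logged count; no imputation is attempted.

## Synthetic-data generator

The generator emulates the structure of a small pediatric CNS tumor cohort
profiled by tandem BS/OxBS (default: 27 tumors — glioma, ependymoma and
embryonal in 13:8:6 proportions — and 3 non-tumor brain controls). It is
the package's test bed: every downstream stage is validated against its
planted truth.

Per-locus baselines:

- A fraction `frac_high5hmc` (default 0.05) of loci carry appreciable 5hmC,
  with baseline levels uniform on [0.10, 0.40]; the rest draw from
  Beta(1.5, 60) (mean ≈ 2.4%, light right tail). High-5hmC loci are drawn
  preferentially from open-sea and enhancer-flagged contexts
  (context weights island 0.1 / shore 0.7 / shelf 1.0 / open sea 2.0,
  enhancer boost 1.6), which produces the island-depletion /
  open-sea-enrichment signature.
- Baseline 5mC is a bimodal mixture (30% Beta(1.5, 8), 70% Beta(6, 2.5)),
  giving the familiar bimodal methylome with median near 0.6.

Planted effects, applied in this order:

1. **DHMR effects**: a `dhmr_frac` subset of the high-5hmC loci receives a
   tumor-specific 5hmC decrement `delta_5hmc` (clipped at zero with a
   logged count when it would go negative) and a 5mC increment `delta_5mc`.
2. **Global tumor hypohydroxymethylation**: every tumor's 5hmC is scaled by
   `tumor_5hmc_scale` (default 0.45).
3. **Two tumor classes**: a `cluster_split` fraction of tumors (default
   0.5) forms a low-5hmC class whose 5hmC is further scaled by
   `low_cluster_scale` (default 0.2).

Because the decrement precedes the multiplicative scalings, the expected
tumor-minus-control gap in true 5hmC at DHMR loci has the closed form
implemented in `expected_dhmr_gap`, and the generator tests assert against
that expectation rather than a nominal constant.

Per-sample biological variability is multiplicative gamma noise on true
5hmC (CV 0.2) and on true 5mC (CV 0.05); true 5mC is then coupled as
m·(1 − h), reflecting that 5hmC is produced by oxidising 5mC. Together with
the shared OxBS read entering both deconvolved estimates with opposite
signs, this yields the predominantly negative per-CpG 5mC–5hmC correlation
across tumors seen in tandem-array data.

Observation noise is beta-distributed with precision `noise_precision`
(default 200, i.e. technical SD ≈ 0.02 at beta 0.08 — array-like); means of
exactly 0/1 are nudged by 1e-6 before sampling, and a `no_noise` flag
returns the means exactly for inversion tests.

Survival: death times are exponential with rate
`baseline_hazard` × `hazard_ratio_low`^{1(low class)} (defaults 0.02/yr and
6.47), recurrence at twice the death rate, both administratively censored
at `censor_time` (15 yr). Ages are integer-uniform 1–18 for tumors and 0–11
for controls; sex is Bernoulli(0.5). Death and recurrence are drawn
independently given class.

The class-separation defaults were chosen by a design calculation: at the
emulated cohort size (27 tumors, 10,000-locus variable panel) the planted
low/high contrast must exceed the per-locus BIC penalty of the clustering
split criterion, otherwise the generator would describe a study whose
two-cluster solution is undiscoverable at its own sample size. With
`low_cluster_scale` = 0.2 and precision 200 the split is accepted and the
classes recovered; weaker contrasts (e.g. scale 0.7) are detectable only at
larger n.

What the generator does **not** emulate: probe-level intensities and
dye/chip batch effects, genomic autocorrelation of methylation state,
realistic gene/CpG-island geometry, correlated death–recurrence outcomes,
tumor purity variation, and the exact medians of any real cohort. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to artefacts the model omits.

## High-5hmC locus selection and summaries

Loci are ranked by median 5hmC across all tumor samples pooled (not a
median of subtype medians) and the top floor(frac·N) are selected; at
frac = 0.05 on a 743,461-locus universe this is exactly 37,173. Ties are
broken by lexicographic locus ID for determinism, and the realised
selection threshold is reported rather than hard-coded. Per-sample medians
are compared between groups by Welch's unequal-variance t-test; groups with
fewer than two samples, or zero-variance medians, yield a flagged
degenerate result instead of a p-value. Per-locus Spearman correlations use
average ranks; zero-variance loci are recorded as undefined and excluded
from the ECDF with a count. TSS profiles are per-bin medians over half-open
bins [lo, lo + bin) partitioning ±window; empty bins report missing, not
zero. Negative TSS distances are upstream. The "total 5hmC" index labels a
tumor High when its mean 5hmC strictly exceeds the median of per-tumor
means.

## Enrichment

All 2×2 tests are built as (in query × in feature) over an explicit
universe — the high-5hmC set against the measured universe, or DHMRs
against the high-5hmC set; the universe is always a parameter, never
implicit. The odds ratio is the unconditional cross-product ratio ad/bc
with a Woolf log-OR normal 95% CI; p-values are two-sided Fisher exact.
Zero cells receive a Haldane–Anscombe 0.5 correction for the OR/CI only and
the row is flagged. Stratified enrichment (by Infinium probe design type)
uses the Mantel–Haenszel common odds ratio Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ) and the
CMH chi-square test; degenerate strata are dropped with a logged count and
a single stratum reduces exactly to the sample OR. Region-set membership
is: a single-base locus at 0-based position p lies in [start, end) iff
start ≤ p < end (BED semantics end to end, no coordinate conversion).
Benjamini–Hochberg q-values are assigned across collections. Gene scoring
keeps genes with at least `min_high` high-5hmC CpGs (default 10) and
reports the percentage of measured CpGs that are high; the alternative
reading — at least 10 measured CpGs regardless of status — is not
implemented because the reported gene count matches the high-CpG rule, but
`min_high` is configurable.

## Differential hydroxymethylation

Each locus gets an OLS fit of 5hmC beta on a group indicator plus age
(years, linear) and sex (binary indicator), vectorised across loci through
one shared design matrix. The group coefficient is the effect (beta scale);
a log2 fold change of group means (1e-6 floor) is reported alongside it
because volcano displays conventionally use it — the two are deliberately
kept distinct. BH q-values are computed across the tested set; DHMRs are
loci with q below the threshold and the requested direction (default hypo).

Optional empirical-Bayes variance moderation (limma-style) shrinks residual
variances toward a scaled-inverse-chi-square prior fitted by method of
moments on the log-variances; it changes only variances and degrees of
freedom, never the effect estimates, and is off by default because the
plain OLS fit is fully specified and testable.

A caveat that matters at small n: under the subtraction estimator,
near-zero loci have zero-inflated 5hmC values, and OLS t p-values there are
anticonservative in the extreme tail (spuriously tiny residual variances).
Two safe configurations, both verified by simulation in the test suite:
restrict the differential scan to the high-5hmC universe (the standard
design, since values there are away from the truncation boundary), or
enable variance moderation for full-universe scans.

## Clustering and survival

`top_variable_loci` ranks loci by 5hmC variance across tumor samples only
(n−1 denominator, lexicographic tie-break). The recursively partitioned
mixture model then clusters tumor profiles:

- at each node a one-class model (independent beta per locus,
  method-of-moments shapes) is compared with a two-class mixture fitted by
  EM: class-specific beta shapes per locus, fuzzy responsibilities, loci
  independent given class;
- EM is initialised from a deterministic two-means split of the profiles
  (Lloyd iterations seeded at the samples with smallest/largest mean beta,
  lexicographic tie-breaks), making the result invariant to sample and
  locus order;
- the M-step uses weighted method-of-moments shape updates (variance floor
  1e-6, precision capped at 1e4, shapes in [1e-3, 1e4]); data are clamped
  to [1e-6, 1−1e-6]; EM runs at most 200 iterations to an absolute
  log-likelihood tolerance of 1e-6, and a non-converged or collapsed node
  is retained unsplit with a logged warning;
- a split is accepted iff BIC improves, counting 2L parameters for the
  one-class model and 4L + 1 for the mixture, and both hard-assigned
  children have at least `min_leaf` members; accepted children recurse to
  `max_depth`.

Guidance on depth: at large sample sizes the per-locus beta model is
misspecified for compounded biological-plus-technical noise, and BIC will
eventually sub-split homogeneous classes — a generic property of mixture
model selection under misspecification. When the analysis targets the
primary bifurcation (a two-class solution), run with `max_depth=1`; the
split can still be rejected, so the one-vs-two-class question remains
honestly tested.

Leaves are labelled high/low 5hmC by mean 5hmC over members and selected
loci (a tie is an error); a Kruskal–Wallis test of per-sample mean 5hmC by
class and Fisher tests of class against subtype are reported as
diagnostics.

Survival uses Cox proportional hazards with Efron tie handling via
lifelines: hazard ratios with Wald 95% CIs, Wald p-values and Harrell's
concordance. Reference levels are female, glioma and the high-5hmC class.
Subjects with missing follow-up are dropped with logged IDs; zero observed
events raise a degenerate-data error; constant covariate columns are
dropped with a warning; runaway coefficients or standard errors (monotone
likelihood / perfect separation) are flagged non-estimable rather than
trusted. Kaplan–Meier curves and the two-group log-rank test complete the
survival surface.

## Pipeline and formats

All tables are TSV with a header and stable column order; matrices carry
the locus ID in the first column. Coordinates are 0-based half-open
everywhere, matching BED, so nothing is converted at file boundaries. The
pipeline writes a manifest (package version, seed, SHA-256 hash of the full
parameter set, per-output row counts) and a plain-text report; identical
configurations produce identical outputs. Any stage failure aborts with the
stage name while earlier outputs remain on disk.

## Problem sizes used in validation

The test suite and acceptance script scale the study design down so that
every check recomputes from scratch: selection arithmetic runs at the full
743,461-locus universe; deconvolution recovery at 2,000 loci × 50 samples;
null-FDR control over 200 replicates of 2,000 loci; clustering/Cox recovery
over 100 replicates of 200 tumors × 200 loci; and the qualitative-signature
run at the default 50,000 loci × 30 samples. These sizes were chosen so the
Monte-Carlo error of each check is small relative to its acceptance margin.

## Known limitations

- The ML deconvolution is per-cell numerical optimisation; use the
  subtraction estimator for array-scale matrices.
- DHMRs are single CpGs; no multi-CpG region smoothing is implemented, and
  "region" in the name follows the field's loose usage.
- The beta-mixture clusterer uses hard leaf membership for downstream
  analysis; fuzzy responsibilities exist internally but are not exposed as
  final assignments.
- p-values from the differential stage inherit the small-sample caveats
  described above; interpret full-universe unmoderated scans with care.
- The generator's region-set collections are synthetic stand-ins for
  external region databases (super-enhancer catalogues etc.); real BED
  collections can be supplied to the same interface.
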