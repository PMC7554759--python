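# Methods

## The quantity of interest

Each RC-L1 locus is either part of the reference assembly (a ~6 kb
interval; individuals lacking the element show a deletion call) or a
non-reference insertion (a breakpoint; carriers show a mobile-element
insertion call). Both are re-expressed on the same scale: the
*presence-allele count*, the number of chromosomes (0/1/2) carrying the
element. An individual's burden over a locus set is the sum of presence
alleles. The analysis asks whether burden — especially of highly active
elements — shifts disease odds, and whether high- and low-burden patients
progress differently.

## Catalog and highly active classification

Coordinates are stored 0-based half-open internally; conversion to and
from 1-based VCF positions happens only at I/O boundaries, which removes
the usual off-by-one ambiguity. Three per-locus activity parameters are
supported, any of which may be missing: assay activity (% of the
L1RP/L1.3 benchmark), germline transduction count, and somatic (tumor)
transduction count.

Highly active (HA) loci are those strictly exceeding the 75th percentile
of at least one *observed* parameter, with percentiles computed over a
stated locus subset (the cohort-polymorphic loci) using linear
interpolation between order statistics by default. The percentile method
is configurable because published threshold values pin the data but not
the algorithm; strict `>` comparison follows the convention of quoting
thresholds as "(>92.3%)". Loci missing a parameter never qualify via
that parameter but can still be HA via another — catalog evidence is
heterogeneous by nature.

## Genotype harmonization

Deletion calls are matched to reference loci when reciprocal overlap
≥ 0.5 *or* both breakpoints fall within 500 bp of the locus ends;
competing candidates resolve by highest reciprocal overlap, then smaller
length difference, each call and locus used at most once. Insertion
calls match non-reference loci within 100 bp, nearest first. These are
standard SV-merging tolerances; they stand in for the original studies'
manual browser-based curation, which is not automatable.

Matched reference genotypes are flipped (presence = 2 − deletion
alleles). A reference locus with no deletion call anywhere in the cohort
is imputed fixed-present (2 for all samples): the deletion caller saw
nobody lacking it. An unmatched non-reference locus is absent (0 for
all). Both imputations are flagged in the per-locus report so downstream
analyses can distinguish imputed from called genotypes.

## Burden, thresholds, association

Burden is computed per sample over a chosen locus set; chrX/chrY loci
can be excluded so male and female genomes are comparable. The default
missingness policy is complete-case: a sample missing any genotype over
the set is flagged and excluded from association (an available-case
rescaled alternative exists but is off by default). Per-locus tests use
available-case samples per locus.

The threshold sweep considers every integer t from the minimum observed
burden to the maximum + 1 and keeps dichotomizations whose smaller
category holds ≥ 5% of controls *and* ≥ 5% of cases, preventing odds
ratios driven by tiny cells. Admissible thresholds form a contiguous
range because both category sizes are monotone in t.

Logistic models are fitted by maximum likelihood (Newton/IRLS, BFGS
fallback) with Wald z inference and CIs `exp(β ± 1.96·SE)`; Wald rather
than profile intervals mirrors standard GWAS tooling. Sex enters as
male = 1, age in years untransformed, family history as two dummies
(first-degree, other; reference none — a binary any-vs-none coding is
available since published covariate codings are rarely stated).
Quasi-separation is flagged when any |β| > 15. Per-locus p values are
Bonferroni-corrected over the loci tested; sweep thresholds are
deliberately *not* multiplicity-corrected — the sweep is reported as a
profile, and the output schema keeps only raw per-threshold p values.

## Longitudinal model

Per clinical feature: `value ~ group + visit + group:visit` with a
per-patient random intercept, fitted by REML (statsmodels MixedLM;
Powell fallback if the default optimizer hits a singular step). Visits
(0/12/24/36 months) are categorical — the question is group differences
at specific visits, not slopes — and random slopes are out of scope.
Estimated marginal means are the fixed-effect predictor at each group ×
visit cell (with only these two factors, the model-based cell mean);
contrasts are per-visit EMM differences with SEs from the fixed-effect
covariance. Inference uses the normal approximation; with cohorts of
hundreds of patients the difference from t-based df corrections is
negligible, and the empirical type-I error of the per-visit contrast is
0.05–0.06 in the package's own null calibration. No multiplicity
adjustment is applied across visits or features, matching the screening
character of the analysis. MoCA-style education-adjusted scores are
treated as pre-adjusted inputs.

## Synthetic data: what it emulates and what it does not

Generators are deterministic given a seed; top-level calls spawn
independent substreams (genotypes, covariates, status, missingness) so
changing the locus set does not perturb covariate draws.

**Catalog.** Assay activity follows a mixture: a bounded low-activity
component (Beta(1,4) scaled to [0, 60]) with weight 0.7 plus a Pareto
tail (scale 60, shape 2) with weight 0.3 — most elements weak, a handful
far above the benchmark, matching the shape of published activity
distributions. Transduction counts are geometric (germline, p = 0.45)
and capped zipf (somatic, a = 1.6). The analytic mixture quantile is
exposed for validation.

**Study-structured catalog.** `make_synthetic_study_catalog` is a
deterministic synthetic stand-in for the published RC-L1 lists (which
are supplementary material of the primary literature and not
redistributable): 81 reference + 117 non-reference loci reproducing the
published marginal summaries exactly — 83 assayed (37/46 by class), 45
below 30% activity, 20 above 100% (54.2% and 24.1% of 83; the closest
integer fractions to the published 54.2%/23.9%), 36 germline and 126
somatic source loci (23/13 and 41/85 by class), and 72 polymorphic loci
whose upper quartiles under linear interpolation are exactly (92.3, 3,
22), yielding 18 HA loci, two of them on chrX, and exactly two loci
exceeding all three thresholds.

**Cohort.** Genotypes are independent Hardy–Weinberg draws per locus
(Binomial(2, af)); fixed reference loci are 2 everywhere, undetected
non-reference loci 0. Case status follows
`logit P = α + γ·1[burden ≥ t*] + β_age(age − 61.5) + β_sex·male + β_fh·famhist`,
with α calibrated by bisection so the expected case fraction matches the
target (default 372/550). Default HA allele frequencies (0.15–0.40,
mean 0.275) give burden mean ≈ 8.6 spanning roughly 2–16, so the ≥9
threshold splits the cohort near 45%/57% as in the motivating study.
The default genotype missing rate (0.004 per entry) reproduces the
observed complete-case attrition (~510 of 550 over 16 loci). Loci are
generated independently: no linkage disequilibrium, no population
structure, no genotyping-error model beyond missingness. Passing tests
therefore demonstrate correctness of the estimators under the assumed
model, not robustness to correlated genotypes or confounded ancestry.

**Longitudinal panels.** `value = cell_mean(group, visit) + b_patient +
ε`, with `b ~ N(0, σ²_patient)` (default 4) and `ε ~ N(0, σ²_residual)`
(default 1) — a compound-symmetry world where the random-intercept model
is exactly correct. Real repeated measures can show serial correlation
and heteroscedasticity the generator does not emulate.

## Simulation sizes and numerical choices

Recovery and calibration checks use sizes chosen to mirror the
motivating study while keeping the whole suite a desk-scale run: CI
coverage of the threshold effect uses 500 replicates at n = 550 with
γ = ln 1.6 (coverage ≈ 0.95 observed, asserted ≥ 0.93); null calibration
of the per-visit contrast uses 500 replicates of 60 patients per group ×
4 visits (a realistic per-feature complete-case size); variance-component
recovery uses 200 patients × 4 visits averaged over 10 seeds (±20%).
Logistic convergence is Newton to statsmodels defaults (rel. tolerance
~1e-8, ≤100 iterations); ties in deletion matching break on length
difference, in insertion matching on lower coordinate. Degenerate inputs
(constant burden, single-class outcomes, constant features, empty locus
sets) raise or are skipped with a logged reason rather than producing
silent numbers.

## Known limitations

* The SV-call matcher is a declared stand-in for manual curation; its
  tolerances (0.5 reciprocal overlap, 500 bp slop, 100 bp insertion
  distance) are conventional, not validated against curated calls.
* Wald inference can misbehave near separation; fits are flagged, not
  corrected (no Firth penalization).
* The normal approximation for mixed-model contrasts is mildly
  anti-conservative for small patient counts.
* Burden weights all HA loci equally; activity-weighted scores are a
  plausible extension not implemented here.
* Whether published per-locus analyses used complete- or available-case
  samples is unstated; per-locus tests here are available-case, burden
  analyses complete-case.
* The direction of published "trend" regressions (status on burden vs
  burden on status) is ambiguous; both forms are provided and neither is
  claimed to reproduce any published coefficient.
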