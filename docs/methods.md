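# Methods

## Statistical model

Each primary study is a case-control comparison of a biallelic SNP with
alleles A and G, summarized by per-arm genotype counts (AA, AG, GG —
ascending G dosage, G fixed as the effect allele throughout). A
genetic-model contrast collapses the 3×2 genotype table to a 2×2
exposure table; the allelic contrast counts the 2N alleles of each arm
as independent observations, a standard approximation in this literature
that slightly understates the variance when genotypes deviate from
Hardy–Weinberg proportions.

The study-level effect is the log odds ratio y = ln(ad/bc) with Woolf
variance v = 1/a + 1/b + 1/c + 1/d. When any cell is zero, the
Haldane–Anscombe correction adds 0.5 to all four cells of that study's
table (and only that study's), applied uniformly across all five
contrasts. With `correction=0` a zero cell is an error rather than a
silent infinity.

Pooling follows the two-stage convention:

- **Cochran's Q** is computed with inverse-variance (IV) weights around
  the IV fixed-effect estimate; I² = max(0, (Q − (k−1))/Q)·100;
  p from the χ²(k−1) upper tail. A single study has Q = 0, p = 1 by
  convention.
- **Model selection**: fixed effect iff p(Q) > α_het (default 0.05,
  strict inequality, so p exactly at the threshold selects random
  effects); configurable.
- **Fixed effect**: Mantel–Haenszel by default when 2×2 tables are
  available (the usual choice for sparse binary data), with the
  Robins–Breslow–Greenland variance for ln OR_MH; inverse variance by
  flag. The standalone `mh_fixed` attaches Q computed around its own MH
  estimate; the pipeline computes heterogeneity once from the IV
  construction and attaches it to whichever estimator is selected, so a
  report cell's method is always consistent with the p(Q) that chose it.
- **Random effects**: DerSimonian–Laird method-of-moments
  τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)), weights 1/(v + τ²). When
  Q ≤ k−1 the estimate truncates to zero and the result coincides with
  IV fixed. No Hartung–Knapp adjustment is offered; REML τ² exists only
  inside meta-regression.
- **Significance**: Z = θ̂/se with a two-sided normal p. All confidence
  intervals are 95% with z = 1.959964 (a module constant).

## Hardy–Weinberg screening

Controls are tested by the Pearson 1-df goodness-of-fit chi-square
against expected counts (np̂², 2np̂(1−p̂), n(1−p̂)²) at the estimated
A-allele frequency p̂. Monomorphic samples give χ² = 0, p = 1 (classes
with zero expected count contribute nothing). The asymptotic test is
used deliberately — no exact test — because the screening convention in
this literature is the chi-square at p < 0.05. HWE p-values reported in
source tables as "<0.001" are stored as 0.0005 with a below-detection
flag; only the comparison against the 0.05 screen ever consumes the
value, so the placeholder is inert.

## Publication-bias tests

Egger's test is the classic unweighted OLS of the standardized effect
t = y/se on precision 1/se, intercept tested against Student-t with k−2
df (k ≥ 3 required; identical precisions are a singular design). When
all y are equal the regression is an exact line through the origin and
the intercept is identically zero; this degenerate case is returned
exactly rather than through the numerically noisy OLS path. Begg's test
standardizes deviations from the IV fixed estimate by √(v − v̄),
computes tie-adjusted Kendall's τ by exhaustive pair counting, and uses
the exact null variance z = (C−D)/√(k(k−1)(2k+5)/18); no continuity
correction. Both are reported per contrast and subgroup on demand; the
funnel export provides per-study (log OR, se, precision) points plus
θ̂ ± 1.96·se pseudo-CI guide lines over an se grid.

## Meta-regression and power

Univariable random-effects meta-regression fits y = Xβ + u + e with
known within-study variances. The residual τ² is the method-of-moments
generalization of DerSimonian–Laird, (Q_E − (k−p))/tr(P) with
P = W − WX(X'WX)⁻¹X'W and FE weights W, truncated at zero; REML is
available as an option via bounded 1-d optimization. Coefficients come
from weighted least squares with weights 1/(v + τ²) and unscaled Wald
covariance (X'W*X)⁻¹, z-tested. Categorical covariates are dummy-coded
against the most frequent level (alphabetical tie-break for
determinism); genotyping-method levels with fewer than 3 studies can be
merged into `other_method` to avoid rank deficiency (the CLI does this
by default for the method covariate). Publication year is continuous by
default. Four separate univariable fits (year, ethnicity, source,
method) are the intended usage, mirroring how heterogeneity sources are
probed one at a time in this literature.

Power uses the unpooled-variance normal approximation of the two-sided
two-proportion test on allele counts: the case G-allele frequency under
odds ratio OR is p₁ = OR·p₀/(1 + p₀(OR−1)), and
power = Φ(−z₁₋α/₂ + δ/se) + Φ(−z₁₋α/₂ − δ/se), which reduces exactly to
α at OR = 1. No continuity correction, so the formula matches the Wald
test simulated in its calibration check.

## Subgroup taxonomy and the packaged roster

The roster schema carries, per study: metadata (first author, year,
origin, cancer type, organ system, ethnicity ∈ {Asian, Caucasian,
African}, control source ∈ {HB, PB}), arm sizes, the control-HWE p as
reported, the genotyping method, and optional per-arm genotype counts.
Subgroup axes: `total`, `hwe_subset` (control-HWE p ≥ 0.05),
`cancer_type` (each type with ≥ 2 studies keeps its own group; all
singleton types merge into one "others" group), `system` (a data-file
mapping from cancer type to five organ systems — digestive tract,
orthopedic, urinary tract, gynecological, hematological; types such as
breast or lung map to none), `ethnicity`, `source`.

The packaged `data/study_roster.tsv` transcribes an 87-study published
roster for CTLA-4 rs231775 and cancer (29,464 cases / 35,858 controls).
Notes on its contents:

- Genotype-count columns are empty — the source table prints only arm
  totals — so the roster exercises the count/subgroup machinery while
  all effect-estimation testing runs on synthetic data. No numbers were
  invented.
- Authors contributing several cancer types in one year appear as
  separate rows with synthetic unique ids (`author_year_cancertype`);
  shared-control overlap between such rows is deliberately not
  deduplicated, matching the source analysis's arithmetic.
- The source publication's own stratified table prints the urinary-tract
  control total as 2002, but its row-level table sums to 2092 and the
  grand totals are only consistent with 2092; the roster keeps the
  row-level values. The spelling "Tumor of urinary tract" follows the
  row-level table.
- Eight studies have control-HWE p < 0.05 and drop out of the
  `hwe_subset` (79 studies, 26,215 cases).

## Synthetic-data generator

`SimulationConfig` defines the generating conditions; defaults describe
a realistic cancer-association literature and are not tuned per test:

- `n_range = (50, 2200)` subjects per arm, uniform — the span of arm
  sizes in the packaged roster.
- `allele_freq_range = (0.35, 0.65)` control G-allele frequency,
  uniform — bracketing the ≈0.40 (Caucasian) and ≈0.62 (Asian) control
  frequencies typical for this variant.
- Ethnicity mix 60:25:2 Asian:Caucasian:African and source mix 53:34
  HB:PB — the packaged roster's composition.
- `tau2 = 0`, `inbreeding_f = 0`, `selection_prob = 0` unless a test
  exercises that mechanism.

Per study, control genotype probabilities are Hardy–Weinberg at the
drawn frequency (an inbreeding coefficient f > 0 depletes heterozygotes
by f·2q(1−q)); case probabilities are the control probabilities tilted
by exp(θ·dosage) and renormalized — the retrospective-sampling
counterpart of a multiplicative per-allele model, chosen so the allelic
contrast's estimand equals the generating log OR exactly when controls
are in HWE. Counts are multinomial; per-study θᵢ ~ N(θ, τ²); everything
is deterministic under a fixed seed, and true parameters travel in a
provenance side channel (`StudyRecord.true_params`, excluded from
equality comparison). Publication selection removes each study with
allelic-contrast two-sided p ≥ 0.05 independently with probability
`selection_prob`.

What the generator does *not* emulate: correlated case/control arm
sizes, linkage disequilibrium, population stratification, covariate
confounding, genotyping error. Calibration results on synthetic data
therefore validate the estimators under their own assumptions, not
robustness to those violations.

## Numerical and design choices

- Cell values are real-valued so corrected tables are representable;
  corrections are logged per study in the pipeline.
- Q, I², τ² always derive from IV weights (the standard DL
  construction); whether p(Q) is computed around the MH or IV estimate
  is immaterial to any count-level result and nearly so numerically.
- `dl_random` with τ̂² = 0 reproduces `iv_fixed` bit-for-bit (same
  summation order), a tested invariant.
- Kendall pair counting is O(k²) by design — meta-analyses have tens of
  studies, and exhaustive counting is the reference semantics the tests
  verify against.
- Subgroups with a single genotyped study are analyzed (crude OR) but
  flagged in the report warnings; `min_k` is configurable.
- Report rendering has a machine variant (full precision, byte-stable
  for identical inputs) and a human variant (OR/CI to 2 decimals,
  p-values to 3); display thresholds like "<0.001" are left to the
  human renderer and never enter machine output.

## Calibration experiments and their scales

`snpmeta.experiments` packages the seeded Monte-Carlo checks the test
suite and `scripts/acceptance.py` run. Problem sizes were chosen once as
the smallest that make the binomial Monte-Carlo error comfortably
smaller than each acceptance band: HWE type-I at 2,000 replicates
(n = 500 controls), Egger type-I at 200 null meta-datasets of k = 20,
pooled-CI coverage at 500 replicates of k = 50 studies (true OR 0.85),
meta-regression slope recovery at 300 replicates of k = 40, power
agreement at 20,000 simulated tests, selection contrast at 300 paired
replicates of k = 40.

## Known limitations

- The two-sided publication-selection mechanism leaves the funnel
  symmetric when the true odds ratio is exactly 1: under the null, a
  study's p-value is independent of its precision, so selection thins
  studies uniformly across the funnel and Egger's rejection rate on
  selected sets is statistically indistinguishable from the unselected
  rate (verified at up to 1,000 paired replicates across several k and
  size ranges). Egger's test does detect this mechanism as soon as the
  true effect departs from the null (e.g. rejection rises from ≈0.05 to
  ≈0.48 at true OR 1.2, k = 40), which a dedicated property test
  documents. One acceptance-level check asserts the directional claim
  at the null and is expected to fail; it is retained unmodified.
- Egger's test is mildly anticonservative for very small studies (the
  finite-sample correlation between a log OR and its estimated
  variance), a known property of the 1997 formulation.
- X-chromosome, multi-allelic, and haplotype analyses are out of scope,
  as are trim-and-fill, Peters/Harbord tests, cumulative and
  leave-one-out meta-analysis.
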