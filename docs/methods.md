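# Methods

## Survey model and derived variables

A participant record carries the raw coded answers of one respondent:
demographics (age in years, sex, rural/urban residency, three-level
education), anthropometrics (weight kg, height m), awareness and
information source, the 13 dichotomous knowledge items, lifestyle
(supplements, alcohol, caffeine, smoking, daily activity band), and
clinical history (falls, fractures, family history, DXA count,
diagnosis, treatment, comorbidities, chronic PPI use). Records are
immutable; the derived variables — BMI, BMI category, knowledge score —
are always recomputed, never stored.

Validation enforces the study design rather than repairing data: age
must be ≥ 40 (the inclusion criterion), the item vector must have
exactly 13 entries, treatment fields must follow the
diagnosis→treatment→type chain, and any missing analysis field rejects
the record outright, mirroring the exclusion of incomplete
questionnaires. Imputation is deliberately absent.

BMI categories use half-open intervals `<18.5`, `[18.5, 25)`,
`[25, 30)`, `[30, ∞)`. The source convention leaves 25.0 and 30.0
formally unassigned ("25–29.9", ">30"); the half-open choice is the
standard WHO reading and makes the categories a true partition of the
positive axis, which a property test asserts.

## Contingency-test policy

Published survey tables of this kind are computed in SPSS, which
switches between the Pearson chi-square and Fisher's exact test by the
smallest expected cell count. The package fixes the policy explicitly:

* expected counts `E_ij = R_i C_j / N`;
* if `min E_ij < 5`: two-sided Fisher exact, probability-mass
  criterion — the sum of hypergeometric probabilities of every
  margin-preserving table no more probable than the observed one (not
  the doubled single tail);
* otherwise: uncorrected Pearson `X²` on 1 df. No Yates correction in
  either branch.

This exact policy reproduces all ten published p-values whose input
counts are printed, at three decimals (seven Pearson, three Fisher) —
the strongest available evidence that it matches the original analysis.
P-values are displayed SPSS-style: three decimals, half-up, `0.000`
only below 0.0005.

The Fisher branch delegates to `scipy.stats.fisher_exact`, whose
two-sided p implements the same probability-mass criterion; the test
suite verifies it against an independent exhaustive enumeration over
every 2×2 table with N ≤ 40 (≈132,000 tables, relative tolerance
1e-7). Mid-range p-values of the exact test sit slightly above
Pearson's (the exact sum is discrete and conservative); empirically the
two agree within 0.02 wherever p < 0.1 at N = 1000, while worst-case
mid-range gaps of ~0.05–0.07 persist — the agreement test is phrased
accordingly.

## Planning formulas and reliability

Single-proportion sample size `n = z² p(1−p) / d²`, rounded to the
nearest integer by default (the conservative ceiling is a flag): with
p = 0.5, 95% confidence and d = 0.08 this plans 150 participants, and
the margin of error at the achieved n = 160 is 7.75 points.

Group comparisons use the equal-variance Student t for two groups
(Welch available as an option) and one-way ANOVA beyond that, with
per-group n/mean/SD reported. Spearman correlation uses average ranks
with the t-approximation p.

Cronbach's α is computed from the variance decomposition
`k/(k−1)·(1 − Σ var_i / var_total)`; the test-retest ICC is the
two-way random-effects, absolute-agreement, single-measure variant
(ICC(2,1)), computed from the two-way ANOVA mean squares. The variant
is a package choice — the source reports an ICC without naming one —
and absolute agreement is preferred because a systematic shift between
sessions should count against reliability. Both coefficients are
cross-checked against pingouin in the tests.

## Knowledge-score regression

OLS of the 0–13 score on six simultaneous predictors: age (years,
continuous), sex (male 0 / female 1), education (ordinal 1/2/3),
residency (rural 0 / urban 1), family history (0/1), diagnosis (0/1).
Ordinal education coding follows the single-coefficient-per-level
layout of the published table; sex coded so a negative coefficient
means lower female scores, matching the published sign. Rank-deficient
designs raise a collinearity error naming constant columns rather than
silently dropping them.

## Synthetic cohort generator

The real joint distribution of the survey population is unknown, so the
generator uses a directed generative chain with explicitly configured
targets:

1. **Demographics** — sex, 10-year age band (uniform age within the
   band, capped at 89 so every record is discretizable), residency,
   education, drawn from the study marginals.
2. **Anthropometrics** — BMI category from its marginal, BMI value from
   a truncated log-normal within the category's support, height normal
   by sex, weight back-solved from BMI.
3. **Clinical** — comorbidities, PPI use, fractures, family history
   from marginals; then diagnosis, DXA uptake, falls, and calcium /
   vitamin D supplementation from logistic links whose odds ratios come
   from the printed 2×2 tables (comorbidities→diagnosis ≈ 4.0,
   fractures→DXA ≈ 4.4, diagnosis→calcium ≈ 17.9,
   diagnosis→vitamin D ≈ 53.6, PPI→falls ≈ 2.2) and whose intercepts
   are solved numerically so the outcome marginal is met in
   expectation.
4. **Knowledge** — 13 conditionally independent Bernoulli items with a
   common base probability (0.404, set so the expected mean score is
   ≈ 7.85/13) plus additive log-odds effects for male (+0.31), urban
   (+0.32), college (+0.55), family history (+0.35) and diagnosis
   (+0.50). By the delta method, a log-odds shift β moves the expected
   score by ≈ 13·p(1−p)·β ≈ 3.1β at p ≈ 0.6, so these defaults
   reproduce the published univariate gaps (≈ +1.0 male, +1.0 urban,
   +1.7 college, +1.1 family history, +1.6 diagnosis). They are
   calibration targets, not ground truth.

What the generator does *not* emulate: within-person correlation of
the knowledge items beyond shared covariates (none is reported);
mediation structure — the real cohort's sex and residency effects
attenuate after adjusting for education, whereas the generator plants
direct effects, so its multivariable fits are stronger (R² ≈ 0.3
vs the published 0.147); and any joint dependence beyond the configured
marginals and pairwise odds ratios. Passing tests therefore show the
machinery is correct under the configured conditions, not that the real
cohort's record-level results are reproduced — those depend on
undeposited data.

`generate_null_cohort` keeps the marginals but sets every odds ratio
to 1 and every effect to 0, giving mutually independent variables for
type-I-error studies.

## Compatibility network

Discretization maps each validated record to four feature classes:
anthropometric (age band 40–49 … 80–89 — ages ≥ 90 are a hard error,
not clamped — BMI category, sex), demographic (education low/high,
high = college; environment), lifestyle (calcium, vitamin D, any
alcohol, coffee, smoking, activity ≥ 30 min/day) and clinical
(fractures, comorbidities, diagnosis, any DXA, treatment). The
published feature list names five lifestyle items against a ≥ 5/6
threshold; vitamin D supplementation, the only remaining binary
lifestyle item in the questionnaire, is used as the sixth and is
configurable.

An edge requires ≥ 3 of 4 class criteria (anthropometric ≥ 2/3,
demographic 2/2, lifestyle ≥ 5/6, clinical ≥ 4/5). Thresholds are data
(`ClassRule` objects), not code, so sensitivity analyses can vary them;
relaxing any threshold can only add edges (a tested monotonicity
property). Construction is vectorized over the O(k²) pair matrix and
verified against the naive pairwise rule on random fixtures; k = 160
builds in milliseconds.

## Communities and enrichment

Community detection uses greedy modularity maximization
(Clauset–Newman–Moore, deterministic ordering) on the subgraph without
isolates — a documented stand-in, since the original analysis used an
unspecified energy-layout clustering in Mathematica and its community
memberships are explicitly not reproduction targets. The stand-in
recovers planted two-block partitions (20+20 nodes, p_in = 0.8,
p_out = 0.05) in ≥ 95 of 100 seeds. Labels are contiguous from 1,
ordered by size descending with smallest-member tie-breaks, so output
is deterministic.

Enrichment ratios divide each feature level's within-community
prevalence by its prevalence over all partitioned nodes (isolates
excluded from the denominator, consistent with their exclusion from the
analysis set). The size-weighted mean of community prevalences
reconstructs the network prevalence exactly — an identity the tests
assert to 1e-9. Display ratios round half-up to one decimal; community
reports flag communities of ≤ 5 members as exploratory.

## Pipeline and problem sizes

The pipeline funnels all randomness through two named seeds (cohort,
community) recorded in a manifest alongside the config hash; identical
configs give byte-identical outputs. Validation failures abort before
any file is written, and a mid-run failure removes partial outputs.

Problem sizes used by the validation experiments: Fisher enumeration
over all tables with N ≤ 40; 100 random 50-profile fixtures for the
edge oracle; 200 replicates of n = 1000 for OLS recovery (planted
education effect 1.0, noise SD 2 on the rounded 0–13 scale); 1000
independence-null cohorts of n = 160 for type-I error, with
smoker×caffeine landing in the Pearson branch and
vitamin D×DXA (rare margins, min expected ≈ 2.1) in the Fisher branch;
100 seeds for planted-partition recovery. These sizes give Monte-Carlo
error comfortably inside the asserted bounds while keeping the whole
validation run in about a minute.
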