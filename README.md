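# osteokap

Analysis toolkit for knowledge–attitudes–practices (KAP) surveys of
osteoporosis in adults aged 40+, modelled on a 160-participant
community-pharmacy survey. It is aimed at epidemiologists and
biostatisticians who need the complete chain — record validation,
derived variables, SPSS-faithful contingency testing, knowledge-score
regression, and participant-compatibility network profiling — as tested,
reusable code, together with a synthetic cohort generator so every stage
runs without access to the original (undeposited) survey records.

## What it computes

**Knowledge score.** Each respondent answers 13 dichotomous knowledge
items; the score is the count of correct answers, `S ∈ {0, …, 13}`,
used as a continuous outcome. BMI = weight/height² is categorized with
half-open WHO cuts (<18.5, [18.5, 25), [25, 30), ≥30).

**2×2 testing policy.** For a contingency table with expected counts
`E_ij = R_i C_j / N`, the package applies the two-sided Fisher exact
test (probability-mass criterion: `p = Σ P(T)` over all
margin-preserving tables `T` with `P(T) ≤ P(observed)`) whenever
`min E_ij < 5`, and the uncorrected Pearson chi-square
`X² = Σ (O−E)²/E` on 1 df otherwise — never a Yates correction. This
policy reproduces published SPSS p-values at three decimals.

**Planning.** Single-proportion sample size `n = z² p(1−p)/d²` and
margin of error `z·√(p(1−p)/n)`.

**Knowledge regression.** OLS of `S` on age (years), sex (female = 1),
education (ordinal 1/2/3), residency (urban = 1), family history and
personal diagnosis, reported as B, SE, t, p with 95% CIs, R², adjusted
R² and the model F. Reliability utilities: Cronbach's α and the
test–retest ICC(2,1).

**Compatibility network.** Each participant is discretized into four
feature classes — anthropometric (10-year age band, BMI category, sex),
demographic (education low/high, rural/urban), lifestyle (6 binaries)
and clinical (5 binaries). An edge joins two participants when at least
3 of the 4 class criteria pass (anthropometric ≥ 2/3, demographic 2/2,
lifestyle ≥ 5/6, clinical ≥ 4/5). Communities are found by greedy
modularity maximization on the non-isolate subgraph, and each community
is profiled by enrichment ratios: prevalence of a feature level inside
the community divided by its prevalence across all partitioned nodes.

**Synthetic cohorts.** `tunis_fixture_config()` encodes the study
marginals (55.6% female, 61.2% urban, 54.1% college, 13.1% diagnosed,
11.3% DXA-tested, …), clinical odds ratios derived from the printed 2×2
tables (e.g. comorbidities→diagnosis OR ≈ 4.0), and knowledge-item
effects calibrated to the published group score gaps.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 0 --out results/analysis
python analysis/04_knowledge_regression.py --input results/analysis/cohort.csv --out results/analysis
python analysis/05_compatibility_network.py --input results/analysis/cohort.csv --out results/analysis
```

prints (seed 0):

```
wrote 160 records -> results/analysis/cohort.csv
  female: 93 (58.1%), diagnosed: 25 (15.6%), mean knowledge score: 7.70/13

                Coefficient  Std. Error  t-Statistic  p-Value
(Constant)            5.427       0.861        6.303    0.000
age                  -0.001       0.011       -0.100    0.920
sex                  -0.890       0.302       -2.945    0.004
education             0.976       0.169        5.762    0.000
residency             0.204       0.312        0.655    0.514
family_history        1.074       0.316        3.394    0.001
diagnosis             1.177       0.408        2.885    0.004
R2=0.300; adj R2=0.272; F(6,153)=10.920, p=0.000

network: 160 nodes, 1831 edges, 4 isolates excluded
communities: sizes [55, 52, 31, 18], modularity 0.267
  community 4 (n=18): osteoporosis_diagnosis=True x7.4, osteoporosis_treatment=True x7.4, ...
```

Education adds ~1 point of knowledge per level and a personal diagnosis
~1.2 points after adjustment, while community 4 concentrates the
diagnosed/treated participants at 7.4× the network prevalence — the
same qualitative structure the method is designed to surface.

The same chain is available as a console script
(`osteokap all --seed 0 --out results/run`), which also writes the
descriptive and crosstab tables plus a run manifest, or as a library
(`osteokap.run_pipeline`).

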