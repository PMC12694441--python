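"""Contingency policy, planning formulas, group tests, OLS, reliability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from osteokap.records import InvalidInputError
from osteokap.stats import (
    CollinearityError, DegenerateTableError,
    pearson_chi2, fisher_exact, crosstab_policy, expected_counts,
    sample_size_single_proportion, margin_of_error,
    compare_groups, spearman_rho, knowledge_ols, design_matrix,
    cronbach_alpha, icc_test_retest, ks_normality, format_p,
)
from tests.conftest import make_record

# The ten published 2x2 tables (rows: predictor no/yes; cols: outcome no/yes)
# with their reported 3-decimal p-values and the test the policy must select.
GOLDEN_TABLES = [
    ("diagnosis~comorbidities", [[99, 8], [40, 13]], "pearson", "0.003"),
    ("falls~comorbidities", [[87, 20], [43, 10]], "pearson", "0.979"),
    ("fractures~comorbidities", [[90, 17], [40, 13]], "pearson", "0.188"),
    ("falls~ppi", [[109, 21], [21, 9]], "pearson", "0.080"),
    ("fractures~ppi", [[106, 24], [24, 6]], "pearson", "0.846"),
    ("dxa~sex", [[65, 6], [77, 12]], "pearson", "0.317"),
    ("dxa~residency", [[57, 5], [85, 13]], "pearson", "0.310"),
    ("dxa~fractures", [[120, 10], [22, 8]], "fisher", "0.007"),
    ("dxa~falls", [[117, 13], [25, 5]], "fisher", "0.336"),
    ("diagnosis~ppi", [[115, 15], [24, 6]], "fisher", "0.234"),
]


@pytest.mark.parametrize("name, table, test_used, p_display",
                         GOLDEN_TABLES, ids=[g[0] for g in GOLDEN_TABLES])
def test_policy_reproduces_published_pvalues(name, table, test_used, p_display):
    res = crosstab_policy(table)
    assert res.test_used == test_used
    assert res.p_display == p_display


def test_policy_selects_by_minimum_expected_count():
    # min expected 30*18/160 = 3.375 < 5 -> fisher
    assert crosstab_policy([[120, 10], [22, 8]]).test_used == "fisher"
    # min expected 53*21/160 ~ 6.96 >= 5 -> pearson
    assert crosstab_policy([[99, 8], [40, 13]]).test_used == "pearson"
    assert expected_counts([[120, 10], [22, 8]]).min() == pytest.approx(3.375)


def test_pearson_is_uncorrected_with_df_one():
    res = pearson_chi2([[10, 10], [10, 10]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1
    # Yates would deflate the statistic; check against scipy's corrected value
    corrected = sps.chi2_contingency([[99, 8], [40, 13]], correction=True)[0]
    assert pearson_chi2([[99, 8], [40, 13]]).statistic > corrected


def test_fisher_symmetric_table_is_one():
    assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)
    assert fisher_exact([[5, 5], [5, 5]]).statistic is None


@pytest.mark.parametrize("table", [[[5, 0], [7, 0]], [[0, 0], [3, 4]]])
def test_zero_margin_is_degenerate(table):
    with pytest.raises(DegenerateTableError):
        crosstab_policy(table)


def _fisher_oracle(a, b, c, d, rtol=1e-7):
    """Exhaustive probability-mass two-sided Fisher over margin-preserving tables."""
    r1, c1, n = a + b, a + c, a + b + c + d
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[support == a][0]
    return pmf[pmf <= p_obs * (1 + rtol)].sum()


def test_fisher_matches_enumeration_on_random_tables(rng):
    for _ in range(200):
        a, b, c, d = rng.integers(0, 15, 4)
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        res = fisher_exact([[a, b], [c, d]])
        assert res.p_value == pytest.approx(
            _fisher_oracle(a, b, c, d), rel=1e-7, abs=1e-12)


def test_large_sample_fisher_and_pearson_agree(rng):
    """With all expected counts >= 5 and N >= 1000 the two tests converge.

    The probability-mass Fisher p runs a little above Pearson's mid-range
    (it is a discrete, conservative sum), so the tight agreement bound is
    checked where test decisions live — small p — with a mean-level bound
    over the whole range.
    """
    diffs, small_p_diffs = [], []
    n = 1000
    while len(diffs) < 100:
        p_row, p_col = rng.uniform(0.2, 0.8, 2)
        x = rng.random(n) < p_row
        flip = rng.random(n) < rng.uniform(0, 0.08)
        y = np.where(flip, x, rng.random(n) < p_col)   # occasional association
        t = np.array([[(~x & ~y).sum(), (~x & y).sum()],
                      [(x & ~y).sum(), (x & y).sum()]])
        if expected_counts(t).min() < 5:
            continue
        p_pearson = pearson_chi2(t).p_value
        d = abs(p_pearson - fisher_exact(t).p_value)
        diffs.append(d)
        if p_pearson < 0.1:
            small_p_diffs.append(d)
    assert np.mean(diffs) < 0.03
    assert max(diffs) < 0.1
    assert len(small_p_diffs) > 10 and max(small_p_diffs) < 0.02


def test_sample_size_planner_closed_form():
    n_exact, n_rounded = sample_size_single_proportion(0.5, 0.95, 0.08)
    assert n_rounded == 150 and n_exact == pytest.approx(150.057, abs=1e-3)
    assert sample_size_single_proportion(0.5, 0.95, 0.05)[1] == 384
    assert sample_size_single_proportion(0.5, 0.95, 0.05, round_up=True)[1] == 385
    # n strictly decreases as the precision requirement relaxes
    ns = [sample_size_single_proportion(0.5, 0.95, d)[0]
          for d in (0.04, 0.06, 0.08, 0.10)]
    assert all(a > b for a, b in zip(ns, ns[1:]))
    with pytest.raises(InvalidInputError):
        sample_size_single_proportion(0.0, 0.95, 0.05)


def test_margin_of_error_scaling():
    moe160 = margin_of_error(160, 0.5, 0.95)
    assert moe160 == pytest.approx(0.0775, abs=5e-4)
    assert moe160 <= 0.08
    assert margin_of_error(640, 0.5, 0.95) == pytest.approx(moe160 / 2)
    assert margin_of_error(100, 0.0, 0.95) == 0.0
    with pytest.raises(InvalidInputError):
        margin_of_error(0, 0.5, 0.95)


def test_compare_groups_dispatch_and_degenerate_cases(rng):
    same = list(range(10))
    res = compare_groups(same + same, ["a"] * 10 + ["b"] * 10)
    assert res.test_used == "t"
    assert res.statistic == pytest.approx(0.0)
    assert res.df == (18,)
    x = rng.normal(size=30)
    res3 = compare_groups(np.concatenate([x, x + 3]),
                          ["a"] * 10 + ["b"] * 10 + ["c"] * 40)
    assert res3.test_used == "anova" and res3.df == (2, 57)
    assert set(res3.group_stats.index) == {"a", "b", "c"}
    with pytest.raises(InvalidInputError):
        compare_groups([1, 2, 3], ["a", "a", "b"])  # group of size 1


def test_welch_option_differs_under_unequal_variance(rng):
    x = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 6, 40)])
    labels = ["a"] * 10 + ["b"] * 40
    student = compare_groups(x, labels, equal_var=True)
    welch = compare_groups(x, labels, equal_var=False)
    assert student.p_value != pytest.approx(welch.p_value, abs=1e-6)


def test_two_sample_power_near_closed_form(rng):
    """Gap 1.0, sd 3.0, n=80/80: power at alpha=.05 should be ~0.56."""
    reps, hits = 500, 0
    for _ in range(reps):
        a = rng.normal(0.0, 3.0, 80)
        b = rng.normal(1.0, 3.0, 80)
        if compare_groups(np.concatenate([a, b]), ["a"] * 80 + ["b"] * 80).p_value < 0.05:
            hits += 1
    assert 0.45 <= hits / reps <= 0.70


def test_spearman_extremes_and_null(rng):
    x = rng.normal(size=50)
    assert spearman_rho(x, x)[0] == pytest.approx(1.0)
    assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)
    with pytest.raises(InvalidInputError):
        spearman_rho(x, np.zeros(50))
    small = sum(abs(spearman_rho(rng.uniform(size=1000),
                                 rng.uniform(size=1000))[0]) < 0.1
                for _ in range(40))
    assert small >= 38  # ~95% of null reps stay inside |rho| < 0.1


def _linear_cohort():
    """Records whose score is an exact linear function of the predictors."""
    records = []
    i = 0
    for edu, edu_code in (("primary", 1), ("high_school", 2), ("college", 3)):
        for sex in ("male", "female"):
            for fam in (False, True):
                for res in ("rural", "urban"):
                    i += 1
                    score = 2 + edu_code + (sex == "female") + 2 * fam
                    # scrambled ages: a sequential age would be an exact
                    # linear combination of the factorial codes
                    records.append(make_record(
                        id=f"L{i:03d}", age_years=40 + (7 * i) % 23, sex=sex,
                        education=edu, residency=res, family_history=fam,
                        knowledge_items=tuple([True] * score + [False] * (13 - score)),
                        osteoporosis_diagnosis=(i % 5 == 0),
                        on_treatment=True if i % 5 == 0 else None,
                        treatment_type="bisphosphonate" if i % 5 == 0 else None,
                    ))
    return records


def test_ols_recovers_noise_free_coefficients_exactly():
    records = _linear_cohort()
    # make the outcome independent of diagnosis/age by construction above
    fit = knowledge_ols(records)
    assert fit.r_squared == pytest.approx(1.0)
    c = fit.coefficients["Coefficient"]
    assert c["education"] == pytest.approx(1.0, abs=1e-8)
    assert c["sex"] == pytest.approx(1.0, abs=1e-8)
    assert c["family_history"] == pytest.approx(2.0, abs=1e-8)
    assert c["residency"] == pytest.approx(0.0, abs=1e-8)
    assert fit.adj_r_squared <= fit.r_squared


def test_ols_table_schema_matches_report_layout(small_cohort):
    fit = knowledge_ols(small_cohort)
    assert list(fit.table().columns) == ["Coefficient", "Std. Error",
                                         "t-Statistic", "p-Value"]
    assert list(fit.coefficients.index) == [
        "(Constant)", "age", "sex", "education", "residency",
        "family_history", "diagnosis"]
    # CI invariant: bounds bracket B with half-width t_crit * SE
    tcrit = sps.t.ppf(0.975, fit.df_residual)
    co = fit.coefficients
    half = (co["CI 97.5%"] - co["CI 2.5%"]) / 2
    assert np.allclose(half, tcrit * co["Std. Error"])
    assert ((co["CI 2.5%"] <= co["Coefficient"])
            & (co["Coefficient"] <= co["CI 97.5%"])).all()


def test_ols_design_coding(small_cohort):
    X = design_matrix(small_cohort[:5])
    assert set(X["sex"]) <= {0, 1} and set(X["education"]) <= {1, 2, 3}


def test_ols_names_collinear_columns(small_cohort):
    records = [r for r in small_cohort if r.residency == "urban"][:30]
    with pytest.raises(CollinearityError, match="residency"):
        knowledge_ols(records)


def test_cronbach_alpha_identities(rng):
    # identical item copies -> alpha 1
    col = rng.integers(0, 2, 100).astype(float)
    assert cronbach_alpha(np.column_stack([col] * 5)) == pytest.approx(1.0)
    # independent items -> alpha ~ 0
    X = rng.integers(0, 2, (2000, 6)).astype(float)
    assert abs(cronbach_alpha(X)) < 0.1
    # two equicorrelated items: alpha equals Spearman-Brown of their correlation
    z = rng.normal(size=5000)
    a_item = z + rng.normal(0, 1, 5000)
    b_item = z + rng.normal(0, 1, 5000)
    r = np.corrcoef(a_item, b_item)[0, 1]
    alpha = cronbach_alpha(np.column_stack([a_item, b_item]))
    assert alpha == pytest.approx(2 * r / (1 + r), abs=0.01)
    with pytest.raises(InvalidInputError):
        cronbach_alpha(np.ones((10, 3)))


def test_cronbach_alpha_agrees_with_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    X = rng.integers(0, 2, (50, 13)).astype(float)
    ours = cronbach_alpha(X)
    theirs = pg.cronbach_alpha(data=pd.DataFrame(X))[0]
    assert ours == pytest.approx(theirs, abs=1e-10)


def test_icc_absolute_agreement_properties(rng):
    s1 = rng.normal(10, 3, 200)
    assert icc_test_retest(s1, s1.copy()) == pytest.approx(1.0)
    # a constant shift is penalised by the absolute-agreement definition
    assert icc_test_retest(s1, s1 + 2.0) < 1.0
    # independent sessions -> ~0
    assert abs(icc_test_retest(rng.normal(size=1000), rng.normal(size=1000))) < 0.1
    with pytest.raises(InvalidInputError):
        icc_test_retest([1, 2, 3], [1, 2])


def test_icc_agrees_with_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    s1 = rng.normal(10, 3, 40)
    s2 = s1 + rng.normal(0.5, 1.5, 40)
    long = pd.DataFrame({
        "subject": list(range(40)) * 2,
        "rater": ["s1"] * 40 + ["s2"] * 40,
        "score": np.concatenate([s1, s2]),
    })
    tab = pg.intraclass_corr(long, targets="subject", raters="rater",
                             ratings="score").set_index("Type")
    # two-way random, absolute agreement, single measure: ICC2 in the
    # Shrout-Fleiss labelling, ICC(A,1) in McGraw-Wong
    label = "ICC2" if "ICC2" in tab.index else "ICC(A,1)"
    assert icc_test_retest(s1, s2) == pytest.approx(float(tab.loc[label, "ICC"]),
                                                    abs=1e-9)


def test_ks_normality_utility(rng):
    stat, p = ks_normality(rng.normal(size=500))
    assert p > 0.01
    with pytest.raises(InvalidInputError):
        ks_normality(np.ones(10))


@pytest.mark.parametrize("p, display", [
    (0.0004999, "0.000"), (0.0005, "0.001"), (0.0026444, "0.003"),
    (0.9785, "0.979"), (0.0805, "0.081"), (1.0, "1.000"), (0.2345, "0.235"),
])
def test_p_display_is_three_decimals_half_up(p, display):
    assert format_p(p) == display
    assert len(format_p(p).split(".")[1]) == 3
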