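"""SPSS-faithful statistical battery for the survey analysis.

The centrepiece is the 2x2 testing policy used throughout the study's
contingency tables: uncorrected Pearson chi-square when every expected
cell count is at least 5, probability-mass two-sided Fisher exact
otherwise, never a Yates continuity correction.  This policy reproduces
the published p-values at three decimals.  The module also provides
group comparisons (Student t / one-way ANOVA), Spearman correlation,
the knowledge-score OLS regression, single-proportion sample-size
planning, and the questionnaire reliability coefficients (Cronbach's
alpha, test-retest ICC).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from osteokap.records import (
    ParticipantRecord, DerivedVariables, derive, InvalidInputError,
)

__all__ = [
    "CrosstabResult", "RegressionFit", "GroupComparison",
    "DegenerateTableError", "CollinearityError",
    "pearson_chi2", "fisher_exact", "crosstab_policy",
    "sample_size_single_proportion", "margin_of_error",
    "compare_groups", "spearman_rho", "knowledge_ols",
    "cronbach_alpha", "icc_test_retest", "ks_normality", "format_p",
]


class DegenerateTableError(ValueError):
    """A 2x2 table with an all-zero row or column margin."""


class CollinearityError(ValueError):
    """Rank-deficient regression design."""


def format_p(p: float) -> str:
    """SPSS-style 3-decimal p display, half-up; '0.000' only when p < 0.0005."""
    return str(Decimal(repr(float(p))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CrosstabResult:
    observed: np.ndarray
    expected: np.ndarray
    test_used: str                 # "pearson" | "fisher"
    statistic: Optional[float]     # None for fisher
    df: Optional[int]
    p_value: float
    p_display: str


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise InvalidInputError(f"expected a 2x2 table, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise InvalidInputError("table entries must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise InvalidInputError("table entries must be nonnegative")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise DegenerateTableError(f"zero margin in table {arr.tolist()}")
    return arr


def expected_counts(table) -> np.ndarray:
    """Expected cell counts under independence: rowsum_i * colsum_j / N."""
    arr = _as_table(table)
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def pearson_chi2(table) -> CrosstabResult:
    """Uncorrected Pearson chi-square on a 2x2 table (df=1, no Yates)."""
    arr = _as_table(table)
    exp = expected_counts(arr)
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return CrosstabResult(observed=arr, expected=exp, test_used="pearson",
                          statistic=float(stat), df=int(df),
                          p_value=float(p), p_display=format_p(p))


def fisher_exact(table) -> CrosstabResult:
    """Two-sided Fisher exact test, probability-mass criterion.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose probability does not exceed that of the
    observed table (the SPSS/scipy convention, not the doubled one tail).
    """
    arr = _as_table(table)
    exp = expected_counts(arr)
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return CrosstabResult(observed=arr, expected=exp, test_used="fisher",
                          statistic=None, df=None,
                          p_value=float(p), p_display=format_p(p))


def crosstab_policy(table) -> CrosstabResult:
    """Select and run the study's 2x2 test: Fisher iff any expected count < 5."""
    arr = _as_table(table)
    if expected_counts(arr).min() < 5:
        return fisher_exact(arr)
    return pearson_chi2(arr)


# ---------------------------------------------------------------------------
# Sample-size planning

def sample_size_single_proportion(p: float, confidence: float, d: float,
                                  round_up: bool = False) -> tuple[float, int]:
    """Minimum n to estimate a single proportion: n = z^2 p(1-p) / d^2.

    ``d`` is the absolute precision (margin of error).  Default rounding
    is to the nearest integer; ``round_up=True`` applies the conservative
    ceiling instead.
    """
    if not (0 < p < 1) or not (0 < d < 1) or not (0 < confidence < 1):
        raise InvalidInputError("p, d and confidence must lie strictly in (0,1)")
    z = float(sps.norm.ppf(0.5 + confidence / 2.0))
    n_exact = z**2 * p * (1 - p) / d**2
    if round_up:
        n_rounded = int(np.ceil(n_exact - 1e-12))
    else:
        n_rounded = int(Decimal(repr(float(n_exact))).quantize(Decimal("1"),
                                                               rounding=ROUND_HALF_UP))
    return float(n_exact), n_rounded


def margin_of_error(n: int, p: float, confidence: float) -> float:
    """Half-width of the normal-approximation CI for a proportion."""
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    if not (0 <= p <= 1) or not (0 < confidence < 1):
        raise InvalidInputError("p in [0,1] and confidence in (0,1) required")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    return float(z * np.sqrt(p * (1 - p) / n))


# ---------------------------------------------------------------------------
# Group comparisons

@dataclass(frozen=True)
class GroupComparison:
    test_used: str                       # "t" | "anova"
    statistic: float
    df: tuple
    p_value: float
    p_display: str
    group_stats: pd.DataFrame            # index group; columns n, mean, sd


def compare_groups(scores: Sequence[float], labels: Sequence,
                   equal_var: bool = True) -> GroupComparison:
    """Student t-test for two groups, one-way ANOVA for more.

    ``equal_var=False`` switches the two-group branch to Welch's t.
    Group means and SDs (ddof=1) are reported alongside the test.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise InvalidInputError("scores and labels must have equal length")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    samples = [scores[labels == g] for g in groups]
    if any(len(s) < 2 for s in samples):
        raise InvalidInputError("every group needs at least two observations")
    table = pd.DataFrame(
        {"n": [len(s) for s in samples],
         "mean": [s.mean() for s in samples],
         "sd": [s.std(ddof=1) for s in samples]},
        index=pd.Index(groups, name="group"))
    if len(groups) == 2:
        stat, p = sps.ttest_ind(samples[0], samples[1], equal_var=equal_var)
        if equal_var:
            df = (len(scores) - 2,)
        else:
            df = (None,)
        return GroupComparison("t", float(stat), df, float(p), format_p(p), table)
    stat, p = sps.f_oneway(*samples)
    df = (len(groups) - 1, len(scores) - len(groups))
    return GroupComparison("anova", float(stat), df, float(p), format_p(p), table)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def ks_normality(x: Sequence[float]) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov statistic against a fitted normal.

    Screening utility only; no automatic switch to non-parametric tests
    is attached to it.
    """
    x = np.asarray(x, dtype=float)
    if x.std(ddof=1) == 0:
        raise InvalidInputError("normality test undefined for constant data")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Knowledge-score OLS

#: regression predictor coding, in the reported order
OLS_PREDICTORS = ("age", "sex", "education", "residency",
                  "family_history", "diagnosis")


@dataclass(frozen=True)
class RegressionFit:
    """Knowledge-score OLS fit in the study's reporting layout.

    ``coefficients`` is indexed by predictor (plus the constant) with
    columns Coefficient, Std. Error, t-Statistic, p-Value and the 95% CI
    bounds; model summary fields mirror the published table footer.
    """
    coefficients: pd.DataFrame
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_p_value: float
    df_model: int
    df_residual: int

    def table(self) -> pd.DataFrame:
        """Exactly the published coefficient columns."""
        return self.coefficients[["Coefficient", "Std. Error", "t-Statistic", "p-Value"]]


def design_matrix(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Predictor coding for the knowledge regression.

    age in years (continuous); sex male=0/female=1; education ordinal
    primary=1/high_school=2/college=3; residency rural=0/urban=1;
    family history and personal diagnosis as 0/1 indicators.
    """
    edu_code = {"primary": 1, "high_school": 2, "college": 3}
    return pd.DataFrame({
        "age": [r.age_years for r in records],
        "sex": [1 if r.sex == "female" else 0 for r in records],
        "education": [edu_code[r.education] for r in records],
        "residency": [1 if r.residency == "urban" else 0 for r in records],
        "family_history": [int(r.family_history) for r in records],
        "diagnosis": [int(r.osteoporosis_diagnosis) for r in records],
    }, index=[r.id for r in records])


def knowledge_ols(records: Sequence[ParticipantRecord],
                  derived: Optional[Sequence[DerivedVariables]] = None) -> RegressionFit:
    """OLS of the 0-13 knowledge score on the six study predictors."""
    import statsmodels.api as sm

    if len(records) < 20:
        raise InvalidInputError(f"need >= 20 complete records, got {len(records)}")
    if derived is None:
        derived = [derive(r) for r in records]
    y = np.array([d.knowledge_score for d in derived], dtype=float)
    X = design_matrix(records)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        constant_cols = [c for c in X.columns if X[c].nunique() == 1]
        raise CollinearityError(
            "rank-deficient design"
            + (f"; constant column(s): {constant_cols}" if constant_cols else ""))
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=0.05)
    coefs = pd.DataFrame({
        "Coefficient": fit.params,
        "Std. Error": fit.bse,
        "t-Statistic": fit.tvalues,
        "p-Value": fit.pvalues,
        "CI 2.5%": ci[0],
        "CI 97.5%": ci[1],
    })
    coefs.index = ["(Constant)"] + list(X.columns)
    return RegressionFit(
        coefficients=coefs,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_p_value=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_residual=int(fit.df_resid),
    )


# ---------------------------------------------------------------------------
# Reliability

def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / score variance)."""
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InvalidInputError("need a respondents x items matrix, >= 2 of each")
    if np.isnan(X).any():
        raise InvalidInputError("missing entries are not allowed")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise InvalidInputError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1 - item_var.sum() / total_var))


def icc_test_retest(session1: Sequence[float], session2: Sequence[float]) -> float:
    """Test-retest ICC: two-way random effects, absolute agreement, single measure.

    The ICC(2,1) variant penalises systematic shifts between sessions,
    which is the property wanted of a test-retest design.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if len(s1) != len(s2):
        raise InvalidInputError("sessions must be paired (equal length)")
    if len(s1) < 3:
        raise InvalidInputError("need at least 3 paired observations")
    n = len(s1)
    data = np.column_stack([s1, s2])          # n subjects x k=2 raters
    k = 2
    grand = data.mean()
    ms_rows = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand
    ms_err = (resid ** 2).sum() / ((n - 1) * (k - 1))
    denom = (ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)
    if denom == 0:
        raise InvalidInputError("ICC undefined: zero between- and within-subject variance")
    return float((ms_rows - ms_err) / denom)
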