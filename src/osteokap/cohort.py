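"""Synthetic survey-cohort generator.

Emulates the statistical structure the downstream analysis assumes: the
marginal frequencies of the study's descriptive tables, group effects on
the 0-13 knowledge score, and the 2x2 associations between clinical
variables, so that every pipeline stage is testable without any data
download.  The generative model is a directed chain — demographics ->
clinical -> behaviors -> knowledge — with logistic links for dependent
binaries and conditionally independent knowledge items; the real joint
distribution of the survey population is unknown, so the configured
marginals and odds ratios are calibration targets, not ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from osteokap.records import ParticipantRecord

__all__ = [
    "CohortConfig", "ConfigurationError", "tunis_fixture_config",
    "generate_cohort", "generate_null_cohort",
]


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


#: age bands usable by the network discretization (10-year intervals)
AGE_BANDS = ("40-49", "50-59", "60-69", "70-79", "80-89")

# BMI category -> (support low, support high, mean of log-BMI, sd of log-BMI)
_DEFAULT_BMI_DIST = {
    "underweight": (15.0, 18.5, math.log(17.3), 0.05),
    "normal": (18.5, 25.0, math.log(21.7), 0.07),
    "overweight": (25.0, 30.0, math.log(27.3), 0.05),
    "obese": (30.0, 42.0, math.log(32.5), 0.07),
}


@dataclass
class CohortConfig:
    """Everything the generator needs: marginals, effects, associations.

    ``marginals`` maps each categorical variable to a level->probability
    table; binary variables carry the probability of the "yes" level.
    ``knowledge_effects`` are additive log-odds shifts applied to every
    knowledge item's correctness probability.  ``association_params`` are
    odds ratios of the predictor->outcome logistic links; the outcome's
    intercept is solved so its configured marginal is met in expectation.
    """

    n: int = 160
    seed: int = 0
    marginals: dict = field(default_factory=dict)
    knowledge_base_prob: float = 0.404
    knowledge_effects: dict = field(default_factory=lambda: {
        "male": 0.0, "urban": 0.0, "college": 0.0,
        "family_history": 0.0, "diagnosed": 0.0,
    })
    association_params: dict = field(default_factory=lambda: {
        "comorbidities_to_diagnosis": 1.0,
        "fracture_history_to_dxa": 1.0,
        "diagnosis_to_calcium": 1.0,
        "diagnosis_to_vitamin_d": 1.0,
        "ppi_to_falls": 1.0,
    })
    bmi_distribution: dict = field(default_factory=lambda: dict(_DEFAULT_BMI_DIST))

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if not (0.0 < self.knowledge_base_prob < 1.0):
            raise ConfigurationError(
                f"knowledge_base_prob must be in (0,1), got {self.knowledge_base_prob}")
        for var, table in self.marginals.items():
            if isinstance(table, dict):
                probs = list(table.values())
                if any(p < 0 or p > 1 for p in probs):
                    raise ConfigurationError(f"{var}: probabilities outside [0,1]")
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"{var}: marginal probabilities sum to {sum(probs)}, not 1")
            else:
                if table < 0 or table > 1:
                    raise ConfigurationError(f"{var}: probability {table} outside [0,1]")
        for name, odds_ratio in self.association_params.items():
            if odds_ratio <= 0:
                raise ConfigurationError(f"{name}: odds ratio must be > 0, got {odds_ratio}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def tunis_fixture_config(n: int = 160, seed: int = 0) -> CohortConfig:
    """Configuration matching the 160-participant Tunis study cohort.

    Marginals reproduce the descriptive frequency tables (55.6% female,
    61.2% urban, 54.1% college, 13.1% diagnosed, 11.3% DXA-tested, ...);
    the odds ratios are computed from the printed 2x2 tables (e.g.
    comorbidities->diagnosis OR = (13/40)/(8/99) ~ 4.0); knowledge-item
    effects are calibrated so univariate group score gaps approximate the
    study's (college vs lower education ~ +1.7 points).
    """
    cfg = CohortConfig(
        n=n,
        seed=seed,
        marginals={
            "sex": {"male": 0.444, "female": 0.556},
            "age_band": {"40-49": 0.225, "50-59": 0.300, "60-69": 0.194,
                         "70-79": 0.150, "80-89": 0.131},
            "residency": {"rural": 0.388, "urban": 0.612},
            "education": {"primary": 0.268, "high_school": 0.191, "college": 0.541},
            "bmi_category": {"underweight": 0.050, "normal": 0.469,
                             "overweight": 0.319, "obese": 0.162},
            "aware_of_osteoporosis": 0.606,
            "info_source": {"physician": 0.557, "family_friends": 0.247,
                            "social_networks": 0.144, "other": 0.052},
            "recent_falls": 0.188,
            "fracture_history": 0.188,
            "calcium_supplement": 0.200,
            "vitamin_d_supplement": 0.119,
            "alcohol": {"none": 0.937, "occasional": 0.025, "regular": 0.038},
            "caffeine": 0.528,
            "smoker": 0.231,
            "activity": {"lt30": 0.587, "m30to60": 0.300, "gt60": 0.113},
            "family_history": 0.313,
            "dxa_ever": 0.113,
            "dxa_twice_given_ever": 5.0 / 18.0,
            "osteoporosis_diagnosis": 0.131,
            "on_treatment_given_diagnosis": 0.952,
            "treatment_type": {"bisphosphonate": 0.75, "raloxifene": 0.20,
                               "calcipotriol": 0.05},
            "comorbidities": 0.331,
            "ppi_over_3_months": 0.1875,
        },
        # base probability chosen so the expected mean score is ~7.85/13
        knowledge_base_prob=0.404,
        knowledge_effects={
            "male": 0.31, "urban": 0.32, "college": 0.55,
            "family_history": 0.35, "diagnosed": 0.50,
        },
        association_params={
            "comorbidities_to_diagnosis": (13 / 40) / (8 / 99),    # ~4.02
            "fracture_history_to_dxa": (8 / 22) / (10 / 120),      # ~4.36
            "diagnosis_to_calcium": (15 / 17) / (6 / 122),         # ~17.9
            "diagnosis_to_vitamin_d": (14 / 5) / (7 / 134),        # ~53.6
            "ppi_to_falls": (9 / 21) / (21 / 109),                 # ~2.22
        },
    )
    cfg.validate()
    return cfg


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _solve_intercept(target: float, predictor_prev: float, odds_ratio: float) -> float:
    """Intercept a such that E[sigmoid(a + log(OR)*X)] = target for X ~ Bern(prev)."""
    beta = math.log(odds_ratio)

    def gap(a: float) -> float:
        return ((1 - predictor_prev) * _sigmoid(a)
                + predictor_prev * _sigmoid(a + beta) - target)

    return brentq(gap, -40.0, 40.0, xtol=1e-12)


def _bernoulli_from_logistic(rng: np.ndarray, intercept: float, beta: float,
                             x: np.ndarray) -> np.ndarray:
    p = _sigmoid(intercept + beta * x.astype(float))
    return rng.random(len(x)) < p


def _draw_categorical(rng, table: dict, n: int) -> np.ndarray:
    levels = list(table.keys())
    probs = np.asarray(list(table.values()), dtype=float)
    probs = probs / probs.sum()  # guard float round-off; validated sum ~ 1
    return rng.choice(levels, size=n, p=probs)


_AGE_BOUNDS = {"40-49": (40, 49), "50-59": (50, 59), "60-69": (60, 69),
               "70-79": (70, 79), "80-89": (80, 89)}
_HEIGHT_BY_SEX = {"male": (1.72, 0.07), "female": (1.60, 0.06)}


def generate_cohort(config: CohortConfig, seed: int | None = None) -> list[ParticipantRecord]:
    """Draw a reproducible synthetic cohort from the configured model.

    Categorical variables follow the configured marginals; dependent
    binaries follow logistic links with the configured odds ratios and
    intercepts solved to hit their marginals in expectation; the 13
    knowledge items are conditionally independent Bernoulli draws with
    additive log-odds group effects.  Every emitted record satisfies the
    survey-model invariants.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n
    m = config.marginals

    sex = _draw_categorical(rng, m["sex"], n)
    age_band = _draw_categorical(rng, m["age_band"], n)
    lo = np.array([_AGE_BOUNDS[b][0] for b in age_band])
    hi = np.array([_AGE_BOUNDS[b][1] for b in age_band])
    age = rng.integers(lo, hi + 1)
    residency = _draw_categorical(rng, m["residency"], n)
    education = _draw_categorical(rng, m["education"], n)

    bmi_cat = _draw_categorical(rng, m["bmi_category"], n)
    bmi = np.empty(n)
    for cat, (low, high, mu, sigma) in config.bmi_distribution.items():
        mask = bmi_cat == cat
        if not mask.any():
            continue
        a, b = (math.log(low) - mu) / sigma, (math.log(high) - mu) / sigma
        draw = truncnorm.rvs(a, b, loc=mu, scale=sigma, size=int(mask.sum()),
                             random_state=rng)
        bmi[mask] = np.exp(draw)
    # keep strictly inside the category's half-open interval
    bmi = np.clip(bmi, 12.0, None)
    h_mu = np.array([_HEIGHT_BY_SEX[s][0] for s in sex])
    h_sd = np.array([_HEIGHT_BY_SEX[s][1] for s in sex])
    height = np.clip(rng.normal(h_mu, h_sd), 1.45, 2.00)
    weight = bmi * height**2

    comorbid = rng.random(n) < m["comorbidities"]
    ppi = rng.random(n) < m["ppi_over_3_months"]
    fracture = rng.random(n) < m["fracture_history"]
    family_hist = rng.random(n) < m["family_history"]
    smoker = rng.random(n) < m["smoker"]
    caffeine = rng.random(n) < m["caffeine"]
    alcohol = _draw_categorical(rng, m["alcohol"], n)
    activity = _draw_categorical(rng, m["activity"], n)

    assoc = config.association_params
    def _linked(outcome_marginal: str, predictor: np.ndarray, or_key: str) -> np.ndarray:
        # intercept solved against the configured predictor marginal, not the
        # sample one, so the link's log-OR is exactly the configured value
        target = m[outcome_marginal]
        a = _solve_intercept(target, _configured_prev(config, or_key), assoc[or_key])
        return _bernoulli_from_logistic(rng, a, math.log(assoc[or_key]), predictor)

    diagnosis = _linked("osteoporosis_diagnosis", comorbid, "comorbidities_to_diagnosis")
    dxa_ever = _linked("dxa_ever", fracture, "fracture_history_to_dxa")
    falls = _linked("recent_falls", ppi, "ppi_to_falls")
    calcium = _linked("calcium_supplement", diagnosis, "diagnosis_to_calcium")
    vitamin_d = _linked("vitamin_d_supplement", diagnosis, "diagnosis_to_vitamin_d")

    dxa_twice = rng.random(n) < m["dxa_twice_given_ever"]
    dxa_count = np.where(dxa_ever, np.where(dxa_twice, 2, 1), 0)

    on_treatment = diagnosis & (rng.random(n) < m["on_treatment_given_diagnosis"])
    treatment_type = _draw_categorical(rng, m["treatment_type"], n)

    aware = rng.random(n) < m["aware_of_osteoporosis"]
    info_source = _draw_categorical(rng, m["info_source"], n)

    eff = config.knowledge_effects
    item_logit = (_logit(config.knowledge_base_prob)
                  + eff.get("male", 0.0) * (sex == "male")
                  + eff.get("urban", 0.0) * (residency == "urban")
                  + eff.get("college", 0.0) * (education == "college")
                  + eff.get("family_history", 0.0) * family_hist
                  + eff.get("diagnosed", 0.0) * diagnosis)
    p_item = _sigmoid(item_logit)
    items = rng.random((n, 13)) < p_item[:, None]

    records = []
    for i in range(n):
        diagnosed = bool(diagnosis[i])
        treated = bool(on_treatment[i]) if diagnosed else None
        records.append(ParticipantRecord(
            id=f"P{i + 1:04d}",
            age_years=int(age[i]),
            sex=str(sex[i]),
            residency=str(residency[i]),
            education=str(education[i]),
            weight=float(weight[i]),
            height=float(height[i]),
            aware_of_osteoporosis=bool(aware[i]),
            info_source=str(info_source[i]) if aware[i] else None,
            knowledge_items=tuple(bool(v) for v in items[i]),
            recent_falls=bool(falls[i]),
            fracture_history=bool(fracture[i]),
            calcium_supplement=bool(calcium[i]),
            vitamin_d_supplement=bool(vitamin_d[i]),
            alcohol=str(alcohol[i]),
            caffeine=bool(caffeine[i]),
            smoker=bool(smoker[i]),
            activity=str(activity[i]),
            family_history=bool(family_hist[i]),
            dxa_count=int(dxa_count[i]),
            osteoporosis_diagnosis=diagnosed,
            on_treatment=treated,
            treatment_type=str(treatment_type[i]) if treated else None,
            comorbidities=bool(comorbid[i]),
            ppi_over_3_months=bool(ppi[i]),
        ))
    return records


def _configured_prev(config: CohortConfig, or_key: str) -> float:
    predictor_marginal = {
        "comorbidities_to_diagnosis": "comorbidities",
        "fracture_history_to_dxa": "fracture_history",
        "ppi_to_falls": "ppi_over_3_months",
        "diagnosis_to_calcium": "osteoporosis_diagnosis",
        "diagnosis_to_vitamin_d": "osteoporosis_diagnosis",
    }[or_key]
    return config.marginals[predictor_marginal]


def generate_null_cohort(n: int, seed: int) -> list[ParticipantRecord]:
    """Cohort with the study marginals but no structure at all.

    Every odds ratio is 1 and every knowledge effect 0, so all variables
    are mutually independent — the type-I-error harness for the
    contingency-testing policy.
    """
    cfg = tunis_fixture_config(n=n, seed=seed)
    cfg.knowledge_effects = {k: 0.0 for k in cfg.knowledge_effects}
    cfg.association_params = {k: 1.0 for k in cfg.association_params}
    return generate_cohort(cfg, seed)
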