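import numpy as np
import pytest

from osteokap.network import DiscreteProfile, AGE_BINS
from osteokap.records import ParticipantRecord


def make_record(**overrides) -> ParticipantRecord:
    """A valid baseline participant; override any field."""
    base = dict(
        id="P0001", age_years=55, sex="female", residency="urban",
        education="college", weight=65.0, height=1.62,
        aware_of_osteoporosis=True, info_source="physician",
        knowledge_items=tuple([True] * 8 + [False] * 5),
        recent_falls=False, fracture_history=False,
        calcium_supplement=False, vitamin_d_supplement=False,
        alcohol="none", caffeine=True, smoker=False, activity="lt30",
        family_history=False, dxa_count=0, osteoporosis_diagnosis=False,
        on_treatment=None, treatment_type=None,
        comorbidities=False, ppi_over_3_months=False,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


def random_profile(rng: np.random.Generator, pid: str) -> DiscreteProfile:
    """Uniformly random discrete profile for network fixtures."""
    return DiscreteProfile(
        id=pid,
        anthropometric=(rng.choice(AGE_BINS),
                        rng.choice(["underweight", "normal", "overweight", "obese"]),
                        rng.choice(["male", "female"])),
        demographic=(rng.choice(["low", "high"]), rng.choice(["rural", "urban"])),
        lifestyle=tuple(bool(b) for b in rng.integers(0, 2, 6)),
        clinical=tuple(bool(b) for b in rng.integers(0, 2, 5)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240201)


@pytest.fixture(scope="session")
def small_cohort():
    from osteokap.cohort import tunis_fixture_config, generate_cohort
    return generate_cohort(tunis_fixture_config(), seed=7)
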