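"""Survey data model: participant records, codebook validation, derived variables.

A :class:`ParticipantRecord` holds the raw coded answers of one respondent
(demographics, anthropometrics, 13 dichotomous knowledge items, lifestyle
and clinical history).  Derived variables — BMI with its WHO category and
the 0-13 knowledge score — are computed, never stored on the raw record.
Records with any missing analysis field are rejected rather than imputed,
mirroring the study's exclusion of incomplete questionnaires.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

N_KNOWLEDGE_ITEMS = 13
MIN_AGE = 40

SEX_LEVELS = ("male", "female")
RESIDENCY_LEVELS = ("rural", "urban")
EDUCATION_LEVELS = ("primary", "high_school", "college")
INFO_SOURCE_LEVELS = ("physician", "family_friends", "social_networks", "other")
ALCOHOL_LEVELS = ("none", "occasional", "regular")
ACTIVITY_LEVELS = ("lt30", "m30to60", "gt60")
TREATMENT_LEVELS = ("bisphosphonate", "raloxifene", "calcipotriol")

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
# Half-open WHO intervals; 30.0 exactly is obese, 25.0 exactly overweight.
_BMI_CUTS = (18.5, 25.0, 30.0)


class InvalidInputError(ValueError):
    """Raised for arguments outside an operation's domain."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One survey respondent, raw coded answers.

    ``knowledge_items`` is an ordered tuple of 13 booleans, True meaning
    the item was answered correctly.  ``on_treatment``/``treatment_type``
    are None unless the participant reports an osteoporosis diagnosis
    (and, for the type, is on treatment).
    """

    id: str
    age_years: int
    sex: str
    residency: str
    education: str
    weight: float          # kg
    height: float          # m
    aware_of_osteoporosis: bool
    info_source: Optional[str]
    knowledge_items: tuple
    recent_falls: bool
    fracture_history: bool
    calcium_supplement: bool
    vitamin_d_supplement: bool
    alcohol: str
    caffeine: bool
    smoker: bool
    activity: str
    family_history: bool
    dxa_count: int
    osteoporosis_diagnosis: bool
    on_treatment: Optional[bool]
    treatment_type: Optional[str]
    comorbidities: bool
    ppi_over_3_months: bool


@dataclass(frozen=True)
class DerivedVariables:
    bmi: float             # kg/m^2
    bmi_category: str
    knowledge_score: int   # 0-13


def compute_bmi(weight: float, height: float) -> tuple[float, str]:
    """BMI (kg/m^2) and its category from weight (kg) and height (m).

    Categories partition (0, inf) into half-open intervals:
    <18.5 underweight, [18.5, 25) normal, [25, 30) overweight, >=30 obese.
    """
    if not (weight > 0) or not (height > 0):
        raise InvalidInputError(
            f"weight and height must be positive, got {weight!r} kg, {height!r} m"
        )
    bmi = weight / height**2
    if bmi < _BMI_CUTS[0]:
        category = "underweight"
    elif bmi < _BMI_CUTS[1]:
        category = "normal"
    elif bmi < _BMI_CUTS[2]:
        category = "overweight"
    else:
        category = "obese"
    return bmi, category


def score_knowledge(items: Sequence[bool]) -> int:
    """Total knowledge score: count of correct answers among the 13 items."""
    items = list(items)
    if len(items) != N_KNOWLEDGE_ITEMS:
        raise InvalidInputError(
            f"expected {N_KNOWLEDGE_ITEMS} knowledge items, got {len(items)}"
        )
    if any(item is None for item in items):
        raise InvalidInputError("knowledge items must not be missing")
    return sum(bool(item) for item in items)


def derive(record: ParticipantRecord) -> DerivedVariables:
    """Compute the derived analysis variables for one record."""
    bmi, category = compute_bmi(record.weight, record.height)
    return DerivedVariables(
        bmi=bmi,
        bmi_category=category,
        knowledge_score=score_knowledge(record.knowledge_items),
    )


def validate_record(record: ParticipantRecord) -> list[str]:
    """Check every record invariant; returns a list of violation messages.

    An empty list means the record is admissible for analysis.  Violations
    name the offending field and the rule, e.g. the age-40 inclusion
    criterion or the 13-item questionnaire length.
    """
    violations: list[str] = []

    def _check(cond: bool, msg: str) -> None:
        if not cond:
            violations.append(msg)

    for f in fields(ParticipantRecord):
        if f.name in ("info_source", "on_treatment", "treatment_type"):
            continue
        if getattr(record, f.name) is None:
            violations.append(f"{f.name}: missing value (incomplete questionnaires are excluded)")

    _check(isinstance(record.age_years, int) and record.age_years >= MIN_AGE,
           f"age_years: must be >= {MIN_AGE} (inclusion criterion), got {record.age_years}")
    _check(record.sex in SEX_LEVELS, f"sex: {record.sex!r} not in {SEX_LEVELS}")
    _check(record.residency in RESIDENCY_LEVELS,
           f"residency: {record.residency!r} not in {RESIDENCY_LEVELS}")
    _check(record.education in EDUCATION_LEVELS,
           f"education: {record.education!r} not in {EDUCATION_LEVELS}")
    _check(record.weight is not None and record.weight > 0,
           f"weight: must be positive, got {record.weight}")
    _check(record.height is not None and record.height > 0,
           f"height: must be positive, got {record.height}")
    _check(len(record.knowledge_items) == N_KNOWLEDGE_ITEMS,
           f"knowledge_items: expected {N_KNOWLEDGE_ITEMS} items, got {len(record.knowledge_items)}")
    _check(all(item is not None for item in record.knowledge_items),
           "knowledge_items: missing answers are not allowed")
    if record.info_source is not None:
        _check(record.info_source in INFO_SOURCE_LEVELS,
               f"info_source: {record.info_source!r} not in {INFO_SOURCE_LEVELS}")
    _check(record.alcohol in ALCOHOL_LEVELS,
           f"alcohol: {record.alcohol!r} not in {ALCOHOL_LEVELS}")
    _check(record.activity in ACTIVITY_LEVELS,
           f"activity: {record.activity!r} not in {ACTIVITY_LEVELS}")
    _check(isinstance(record.dxa_count, int) and record.dxa_count >= 0,
           f"dxa_count: must be a nonnegative integer, got {record.dxa_count}")
    # treatment fields are conditional on the diagnosis chain
    if record.on_treatment is not None and not record.osteoporosis_diagnosis:
        violations.append("on_treatment: present without an osteoporosis diagnosis")
    if record.treatment_type is not None:
        if not record.on_treatment:
            violations.append("treatment_type: present without on_treatment")
        elif record.treatment_type not in TREATMENT_LEVELS:
            violations.append(
                f"treatment_type: {record.treatment_type!r} not in {TREATMENT_LEVELS}")
    if record.on_treatment and record.treatment_type is None:
        violations.append("treatment_type: missing for a treated participant")
    return violations


# ---------------------------------------------------------------------------
# CSV interface

CODEBOOK_VERSION = "1.0"

_BOOL_COLS = (
    "aware_of_osteoporosis", "recent_falls", "fracture_history",
    "calcium_supplement", "vitamin_d_supplement", "caffeine", "smoker",
    "family_history", "osteoporosis_diagnosis", "comorbidities",
    "ppi_over_3_months",
)
_KNOW_COLS = tuple(f"k{i:02d}" for i in range(1, N_KNOWLEDGE_ITEMS + 1))

CSV_COLUMNS = (
    ("id", "free text, unique"),
    ("age_years", "integer >= 40"),
    ("sex", "|".join(SEX_LEVELS)),
    ("residency", "|".join(RESIDENCY_LEVELS)),
    ("education", "|".join(EDUCATION_LEVELS)),
    ("weight", "kg, positive real"),
    ("height", "m, positive real"),
    ("aware_of_osteoporosis", "0|1"),
    ("info_source", "|".join(INFO_SOURCE_LEVELS) + "|empty"),
    *((c, "0|1 (1 = correct answer)") for c in _KNOW_COLS),
    ("recent_falls", "0|1"),
    ("fracture_history", "0|1"),
    ("calcium_supplement", "0|1"),
    ("vitamin_d_supplement", "0|1"),
    ("alcohol", "|".join(ALCOHOL_LEVELS)),
    ("caffeine", "0|1"),
    ("smoker", "0|1"),
    ("activity", "|".join(ACTIVITY_LEVELS) + " (minutes/day)"),
    ("family_history", "0|1"),
    ("dxa_count", "integer >= 0"),
    ("osteoporosis_diagnosis", "0|1"),
    ("on_treatment", "0|1|empty (present only if diagnosed)"),
    ("treatment_type", "|".join(TREATMENT_LEVELS) + "|empty"),
    ("comorbidities", "0|1"),
    ("ppi_over_3_months", "0|1"),
)


def codebook_text() -> str:
    """Versioned plain-text codebook: column name -> allowed codes."""
    lines = [f"# osteokap cohort CSV codebook v{CODEBOOK_VERSION}",
             "# column\tallowed codes"]
    lines += [f"{name}\t{codes}" for name, codes in CSV_COLUMNS]
    return "\n".join(lines) + "\n"


def _fmt_bool(v: Optional[bool]) -> str:
    return "" if v is None else str(int(v))


def write_cohort_csv(records: Iterable[ParticipantRecord], path: str | Path,
                     codebook: bool = True) -> None:
    """Write one row per participant (UTF-8); optionally the codebook beside it."""
    path = Path(path)
    header = [name for name, _ in CSV_COLUMNS]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            row = [
                r.id, r.age_years, r.sex, r.residency, r.education,
                repr(float(r.weight)), repr(float(r.height)),
                _fmt_bool(r.aware_of_osteoporosis),
                r.info_source or "",
                *(str(int(bool(k))) for k in r.knowledge_items),
                _fmt_bool(r.recent_falls), _fmt_bool(r.fracture_history),
                _fmt_bool(r.calcium_supplement), _fmt_bool(r.vitamin_d_supplement),
                r.alcohol, _fmt_bool(r.caffeine), _fmt_bool(r.smoker),
                r.activity, _fmt_bool(r.family_history), r.dxa_count,
                _fmt_bool(r.osteoporosis_diagnosis), _fmt_bool(r.on_treatment),
                r.treatment_type or "",
                _fmt_bool(r.comorbidities), _fmt_bool(r.ppi_over_3_months),
            ]
            writer.writerow(row)
    if codebook:
        path.with_suffix(".codebook.txt").write_text(codebook_text(), encoding="utf-8")


def _parse_bool(s: str, col: str) -> Optional[bool]:
    if s == "":
        return None
    if s not in ("0", "1"):
        raise InvalidInputError(f"{col}: expected 0/1, got {s!r}")
    return s == "1"


def read_cohort_csv(path: str | Path, validate: bool = True) -> list[ParticipantRecord]:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    With ``validate=True`` (default) any record violating the codebook
    raises, naming the offending record ids.
    """
    records: list[ParticipantRecord] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            records.append(ParticipantRecord(
                id=row["id"],
                age_years=int(row["age_years"]),
                sex=row["sex"],
                residency=row["residency"],
                education=row["education"],
                weight=float(row["weight"]),
                height=float(row["height"]),
                aware_of_osteoporosis=_parse_bool(row["aware_of_osteoporosis"],
                                                  "aware_of_osteoporosis"),
                info_source=row["info_source"] or None,
                knowledge_items=tuple(_parse_bool(row[c], c) for c in _KNOW_COLS),
                recent_falls=_parse_bool(row["recent_falls"], "recent_falls"),
                fracture_history=_parse_bool(row["fracture_history"], "fracture_history"),
                calcium_supplement=_parse_bool(row["calcium_supplement"], "calcium_supplement"),
                vitamin_d_supplement=_parse_bool(row["vitamin_d_supplement"],
                                                 "vitamin_d_supplement"),
                alcohol=row["alcohol"],
                caffeine=_parse_bool(row["caffeine"], "caffeine"),
                smoker=_parse_bool(row["smoker"], "smoker"),
                activity=row["activity"],
                family_history=_parse_bool(row["family_history"], "family_history"),
                dxa_count=int(row["dxa_count"]),
                osteoporosis_diagnosis=_parse_bool(row["osteoporosis_diagnosis"],
                                                   "osteoporosis_diagnosis"),
                on_treatment=_parse_bool(row["on_treatment"], "on_treatment"),
                treatment_type=row["treatment_type"] or None,
                comorbidities=_parse_bool(row["comorbidities"], "comorbidities"),
                ppi_over_3_months=_parse_bool(row["ppi_over_3_months"], "ppi_over_3_months"),
            ))
    if validate:
        bad = {r.id: validate_record(r) for r in records}
        bad = {rid: v for rid, v in bad.items() if v}
        if bad:
            detail = "; ".join(f"{rid}: {v[0]}" for rid, v in list(bad.items())[:5])
            raise InvalidInputError(
                f"{len(bad)} invalid record(s): {detail}")
    return records
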