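"""The 2x2 testing batteries: DXA uptake, prevention behaviours, comorbidity/PPI.

Each battery applies the expected-count policy (Fisher iff any expected
cell < 5, otherwise uncorrected Pearson chi-square) and reports which
test was selected and the 3-decimal p-value, mirroring the published
contingency tables' layout.
"""

import argparse
from pathlib import Path

import pandas as pd

from osteokap.pipeline import _crosstab_battery
from osteokap.records import read_cohort_csv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--input", type=Path, default=Path("results/analysis/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cohort = read_cohort_csv(args.input)
    args.out.mkdir(parents=True, exist_ok=True)

    batteries = {
        "dxa_crosstabs": (lambda r: r.dxa_count >= 1, {
            "sex_female": lambda r: r.sex == "female",
            "residency_urban": lambda r: r.residency == "urban",
            "recent_falls": lambda r: r.recent_falls,
            "fracture_history": lambda r: r.fracture_history,
        }),
        "prevention_crosstabs": (lambda r: r.osteoporosis_diagnosis, {
            "calcium_supplement": lambda r: r.calcium_supplement,
            "vitamin_d_supplement": lambda r: r.vitamin_d_supplement,
        }),
        "comorbidity_ppi_crosstabs": (lambda r: r.osteoporosis_diagnosis, {
            "comorbidities": lambda r: r.comorbidities,
            "ppi_over_3_months": lambda r: r.ppi_over_3_months,
        }),
    }
    for name, (outcome, predictors) in batteries.items():
        table = _crosstab_battery(cohort, outcome, predictors)
        table.to_csv(args.out / f"{name}.csv", index=False)
        summary = ", ".join(f"{row.predictor}: {row.test_used} p={row.p}"
                            for row in table.itertuples())
        print(f"{name}: {summary}")


if __name__ == "__main__":
    main()
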