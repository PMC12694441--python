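"""Multiple linear regression of the knowledge score on the six predictors.

Age (years), sex (female=1), education (ordinal 1-3), residency
(urban=1), family history and personal diagnosis entered simultaneously;
reports coefficients with 95% CIs and the model summary.
"""

import argparse
from pathlib import Path

from osteokap.records import read_cohort_csv
from osteokap.stats import format_p, knowledge_ols


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--input", type=Path, default=Path("results/analysis/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cohort = read_cohort_csv(args.input)
    fit = knowledge_ols(cohort)
    args.out.mkdir(parents=True, exist_ok=True)
    fit.coefficients.to_csv(args.out / "knowledge_ols.csv")

    print(fit.table().round(3).to_string())
    print(f"R2={fit.r_squared:.3f}; adj R2={fit.adj_r_squared:.3f}; "
          f"F({fit.df_model},{fit.df_residual})={fit.f_statistic:.3f}, "
          f"p={format_p(fit.f_p_value)}")


if __name__ == "__main__":
    main()
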