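"""End-to-end orchestration of the survey analysis.

``run_pipeline`` takes a cohort (a CSV in the codebook layout, or a
synthetic one generated on the fly), validates every record, and emits
the study's full output set in order: descriptive frequency tables,
knowledge-score group comparisons, the three crosstab batteries (DXA
uptake, prevention behaviours, comorbidity/PPI), the knowledge OLS
regression, and the compatibility network with its community partition
and enrichment report, plus a manifest recording seeds, config hash and
software version.  All randomness flows through two named seeds (cohort
seed, community seed); two runs with the same config produce
byte-identical outputs.
"""

from __future__ import annotations

import argparse
import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from osteokap import records as rec
from osteokap import stats as st
from osteokap.cohort import CohortConfig, tunis_fixture_config, generate_cohort
from osteokap.communities import detect_communities, enrichment_ratios, community_report
from osteokap.network import (
    default_class_rules, discretize_profile, build_graph,
    write_edge_list, write_graphml,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "main"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """One run of the full analysis.

    Exactly one input mode is active: ``csv_path`` to analyze an existing
    cohort file, or ``synthetic=True`` to generate one from
    ``cohort_config`` (defaults to the study-cohort configuration).
    ``class_rule_minima`` overrides the per-class match thresholds.
    """
    csv_path: Optional[str] = None
    synthetic: bool = True
    cohort_config: Optional[CohortConfig] = None
    cohort_seed: int = 0
    community_seed: int = 0
    min_classes: int = 3
    class_rule_minima: Optional[dict] = None
    output_dir: str = "results"
    output_format: str = "csv"          # "csv" | "json"

    def validate(self) -> None:
        if (self.csv_path is not None) == self.synthetic:
            raise PipelineError("exactly one input mode: csv_path or synthetic")
        if self.output_format not in ("csv", "json"):
            raise PipelineError(f"unknown output format {self.output_format!r}")


def _freq_table(records: list[rec.ParticipantRecord]) -> pd.DataFrame:
    derived = [rec.derive(r) for r in records]
    rows = []

    def add(var, values):
        counts = pd.Series(values).value_counts()
        n = len(values)
        for level, c in counts.items():
            rows.append({"variable": var, "group": str(level),
                         "count": int(c), "percent": round(100 * c / n, 1)})

    add("sex", [r.sex for r in records])
    add("age_band", [f"{(r.age_years - 40) // 10 * 10 + 40}s" for r in records])
    add("residency", [r.residency for r in records])
    add("education", [r.education for r in records])
    add("aware_of_osteoporosis", [r.aware_of_osteoporosis for r in records])
    add("info_source", [r.info_source for r in records if r.info_source])
    add("bmi_category", [d.bmi_category for d in derived])
    for var in ("recent_falls", "fracture_history", "calcium_supplement",
                "vitamin_d_supplement", "caffeine", "smoker", "family_history",
                "osteoporosis_diagnosis", "comorbidities", "ppi_over_3_months"):
        add(var, [getattr(r, var) for r in records])
    add("alcohol", [r.alcohol for r in records])
    add("activity", [r.activity for r in records])
    add("dxa_ever", [r.dxa_count >= 1 for r in records])
    diagnosed = [r for r in records if r.osteoporosis_diagnosis]
    if diagnosed:
        add("on_treatment", [bool(r.on_treatment) for r in diagnosed])
        treated = [r.treatment_type for r in diagnosed if r.treatment_type]
        if treated:
            add("treatment_type", treated)
    return pd.DataFrame(rows)


#: grouping variables of the knowledge-score comparison table
_GROUPERS = {
    "sex": lambda r, d: r.sex,
    "age_band": lambda r, d: f"{(r.age_years - 40) // 10 * 10 + 40}s",
    "residency": lambda r, d: r.residency,
    "education": lambda r, d: r.education,
    "recent_falls": lambda r, d: r.recent_falls,
    "family_history": lambda r, d: r.family_history,
    "osteoporosis_diagnosis": lambda r, d: r.osteoporosis_diagnosis,
    "bmi_category": lambda r, d: d.bmi_category,
    "activity": lambda r, d: r.activity,
}


def _knowledge_table(records) -> pd.DataFrame:
    derived = [rec.derive(r) for r in records]
    scores = [d.knowledge_score for d in derived]
    rows = []
    for var, key in _GROUPERS.items():
        labels = [str(key(r, d)) for r, d in zip(records, derived)]
        try:
            cmp_res = st.compare_groups(scores, labels)
            p_disp, test = cmp_res.p_display, cmp_res.test_used
            stats_tbl = cmp_res.group_stats
        except rec.InvalidInputError:
            p_disp, test = "", "insufficient"
            df_labels = pd.Series(labels)
            stats_tbl = pd.DataFrame({
                "n": df_labels.value_counts(),
                "mean": pd.Series(scores).groupby(df_labels).mean(),
                "sd": pd.Series(scores).groupby(df_labels).std(),
            })
        for group, row in stats_tbl.iterrows():
            rows.append({"variable": var, "group": group, "n": int(row["n"]),
                         "mean": round(row["mean"], 2),
                         "sd": round(row["sd"], 2) if pd.notna(row["sd"]) else None,
                         "test": test, "p": p_disp})
    return pd.DataFrame(rows)


def _crosstab_battery(records, outcome_getter, predictors) -> pd.DataFrame:
    """2x2 policy tests of one binary outcome against several binary predictors."""
    rows = []
    for name, pred in predictors.items():
        tab = [[0, 0], [0, 0]]
        for r in records:
            tab[int(bool(pred(r)))][int(bool(outcome_getter(r)))] += 1
        try:
            res = st.crosstab_policy(tab)
            rows.append({
                "predictor": name,
                "n00": tab[0][0], "n01": tab[0][1],
                "n10": tab[1][0], "n11": tab[1][1],
                "pct_outcome_given_no": round(100 * tab[0][1] / max(sum(tab[0]), 1), 1),
                "pct_outcome_given_yes": round(100 * tab[1][1] / max(sum(tab[1]), 1), 1),
                "test_used": res.test_used,
                "statistic": res.statistic,
                "p": res.p_display,
            })
        except (st.DegenerateTableError, rec.InvalidInputError):
            rows.append({"predictor": name, "n00": tab[0][0], "n01": tab[0][1],
                         "n10": tab[1][0], "n11": tab[1][1],
                         "pct_outcome_given_no": None, "pct_outcome_given_yes": None,
                         "test_used": "degenerate", "statistic": None, "p": ""})
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path, fmt: str) -> Path:
    if fmt == "json":
        path = path.with_suffix(".json")
        path.write_text(df.to_json(orient="records", indent=2), encoding="utf-8")
    else:
        path = path.with_suffix(".csv")
        df.to_csv(path, index=False)
    return path


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage; returns the artifact name -> path map.

    Validation failures abort with the offending record ids before any
    output is written; a failure mid-run removes partial outputs.
    """
    from osteokap import __version__

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic:
        cohort_cfg = config.cohort_config or tunis_fixture_config()
        records = generate_cohort(cohort_cfg, config.cohort_seed)
        cfg_dict = dataclasses.asdict(cohort_cfg)
    else:
        records = rec.read_cohort_csv(config.csv_path, validate=False)
        cfg_dict = {"csv_path": str(config.csv_path)}

    bad = {r.id: v for r in records if (v := rec.validate_record(r))}
    if bad:
        detail = "; ".join(f"{rid}: {v[0]}" for rid, v in list(bad.items())[:10])
        raise PipelineError(
            f"aborting: {len(bad)} record(s) violate the inclusion/validation "
            f"rules — {detail}")

    artifacts: dict[str, Path] = {}
    written: list[Path] = []
    fmt = config.output_format
    try:
        def emit(name: str, df: pd.DataFrame) -> None:
            p = _write(df, out / name, fmt)
            artifacts[name] = p
            written.append(p)
            print(f"[osteokap] {name}: {len(df)} rows -> {p}", file=sys.stderr)

        emit("table1_2_descriptives", _freq_table(records))
        emit("table3_knowledge_groups", _knowledge_table(records))
        emit("table4_dxa_crosstabs", _crosstab_battery(
            records, lambda r: r.dxa_count >= 1, {
                "sex_female": lambda r: r.sex == "female",
                "residency_urban": lambda r: r.residency == "urban",
                "recent_falls": lambda r: r.recent_falls,
                "fracture_history": lambda r: r.fracture_history,
            }))
        emit("table5_prevention_crosstabs", _crosstab_battery(
            records, lambda r: r.osteoporosis_diagnosis, {
                "calcium_supplement": lambda r: r.calcium_supplement,
                "vitamin_d_supplement": lambda r: r.vitamin_d_supplement,
            }))
        t6 = []
        for outcome_name, getter in (
                ("osteoporosis_diagnosis", lambda r: r.osteoporosis_diagnosis),
                ("recent_falls", lambda r: r.recent_falls),
                ("fracture_history", lambda r: r.fracture_history)):
            part = _crosstab_battery(records, getter, {
                "comorbidities": lambda r: r.comorbidities,
                "ppi_over_3_months": lambda r: r.ppi_over_3_months,
            })
            part.insert(0, "outcome", outcome_name)
            t6.append(part)
        emit("table6_comorbidity_ppi_crosstabs", pd.concat(t6, ignore_index=True))

        fit = st.knowledge_ols(records)
        coefs = fit.coefficients.reset_index(names="predictor")
        coefs["model"] = (f"R2={fit.r_squared:.3f}; adjR2={fit.adj_r_squared:.3f}; "
                          f"F={fit.f_statistic:.3f}; p={st.format_p(fit.f_p_value)}")
        emit("table7_knowledge_ols", coefs)

        rules = default_class_rules()
        if config.class_rule_minima:
            rules = {name: dataclasses.replace(rule, min_matches=config.class_rule_minima.get(name, rule.min_matches))
                     for name, rule in rules.items()}
        profiles = [discretize_profile(r) for r in records]
        G = build_graph(profiles, rules, config.min_classes)
        edge_path = out / "network_edges.tsv"
        write_edge_list(G, edge_path)
        artifacts["network_edges"] = edge_path
        written.append(edge_path)
        gml_path = out / "network.graphml"
        write_graphml(G, gml_path)
        artifacts["network_graphml"] = gml_path
        written.append(gml_path)

        partition = detect_communities(G, seed=config.community_seed)
        part_df = pd.DataFrame(sorted(partition.assignment.items()),
                               columns=["id", "community"])
        emit("communities", part_df)
        enr = enrichment_ratios(partition, profiles)
        emit("enrichment", enr)
        emit("community_report", community_report(partition, enr))

        manifest = {
            "software": "osteokap",
            "version": __version__,
            "cohort_seed": config.cohort_seed,
            "community_seed": config.community_seed,
            "n_records": len(records),
            "n_edges": G.number_of_edges(),
            "n_isolates": len(partition.isolates),
            "n_communities": partition.n_communities,
            "modularity": round(partition.modularity, 6),
            "min_classes": config.min_classes,
            "class_rule_minima": {n: r.min_matches for n, r in rules.items()},
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest(),
        }
        man_path = out / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                            encoding="utf-8")
        artifacts["manifest"] = man_path
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return artifacts


# ---------------------------------------------------------------------------
# CLI

def _build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="osteokap",
        description="Osteoporosis KAP-survey analysis pipeline")
    sub = parser.add_subparsers(dest="command", required=True)

    def common(p):
        p.add_argument("--config", help="cohort config JSON (synthetic mode)")
        p.add_argument("--input", help="cohort CSV (analysis of an existing file)")
        p.add_argument("--seed", type=int, default=0,
                       help="cohort seed (community seed derives from it)")
        p.add_argument("--out", default="results", help="output directory")
        p.add_argument("--format", choices=("csv", "json"), default="csv")

    for name in ("simulate", "analyze", "network", "report", "all"):
        common(sub.add_parser(name))
    sub.choices["simulate"].add_argument("--n", type=int, default=160)
    return parser


def _config_from_args(args) -> PipelineConfig:
    cohort_cfg = CohortConfig.from_json(args.config) if args.config else None
    return PipelineConfig(
        csv_path=args.input,
        synthetic=args.input is None,
        cohort_config=cohort_cfg,
        cohort_seed=args.seed,
        community_seed=args.seed + 1,
        output_dir=args.out,
        output_format=args.format,
    )


def main(argv: Optional[list[str]] = None) -> int:
    args = _build_parser().parse_args(argv)
    if args.command == "simulate":
        cfg = (CohortConfig.from_json(args.config) if args.config
               else tunis_fixture_config(n=args.n))
        records = generate_cohort(cfg, args.seed)
        out = Path(args.out)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "cohort.csv"
        rec.write_cohort_csv(records, path)
        print(f"[osteokap] wrote {len(records)} records -> {path}", file=sys.stderr)
        return 0
    # analyze/network/report/all share the full pipeline; the stages are
    # cheap enough that partial runs are not worth separate code paths
    artifacts = run_pipeline(_config_from_args(args))
    print(f"[osteokap] {len(artifacts)} artifacts in {args.out}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
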