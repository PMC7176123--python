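"""Survey-weighted prevalence tables and district-level summaries.

Produces the descriptive layer of the analysis: overall weighted prevalence
of each condition with 95% CIs, prevalence stratified by socio-demographic
factors (the classic survey-table shape), self-report validity against the
measured definitions, and per-district prevalences whose instability
motivates the spatial smoothing model.
"""

from pathlib import Path

import pandas as pd

from cvdmap import outcomes as oc
from cvdmap import survey
from cvdmap.spatial_graph import read_adjacency

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT = Path(__file__).resolve().parent.parent / "results" / "survey"

STRATIFIERS = ["sex", "age_group", "education", "locality", "race",
               "bmi_class", "smoking", "alcohol", "diabetes", "wealth_quintile"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = oc.read_participants(SIM / "participants.csv")
    graph = read_adjacency(SIM / "adjacency.txt", "winbugs_adj")
    Y, _ = oc.derive_outcomes(records)
    w = records["interview_weight"]

    overall = []
    for cond in oc.OUTCOME_NAMES:
        est = survey.weighted_prevalence(Y[cond], w)
        overall.append({"condition": cond, "p_hat": est.p_hat,
                        "ci_low": est.ci_low, "ci_high": est.ci_high, "n": est.n})
        print(f"{cond:7s} {100 * est.p_hat:5.1f}% "
              f"({100 * est.ci_low:.1f}-{100 * est.ci_high:.1f})  n={est.n}")
    pd.DataFrame(overall).to_csv(OUT / "prevalence_overall.csv", index=False)

    tables = []
    for cond in oc.OUTCOME_NAMES:
        for strat in STRATIFIERS:
            col = Y["diabetes"] if strat == "diabetes" else records[strat]
            t = survey.stratified_prevalence(Y[cond], w, col)
            t.insert(0, "condition", cond)
            t.insert(1, "factor", strat)
            tables.append(t)
    pd.concat(tables).to_csv(OUT / "prevalence_stratified.csv", index=False)

    # self-report validity: measured-only definitions as gold standard
    sbp, dbp = records["sbp"], records["dbp"]
    measured_hbp = ((sbp >= oc.SBP_CUTOFF) | (dbp >= oc.DBP_CUTOFF)).where(
        sbp.notna() | dbp.notna()
    )
    v = survey.sensitivity_specificity(records["self_hbp"], measured_hbp)
    print(f"self-reported HBP vs measured: sensitivity {v.sensitivity:.3f}, "
          f"specificity {v.specificity:.3f}")

    district_tables = []
    for cond in oc.OUTCOME_NAMES:
        table, summary = survey.district_prevalence(
            Y[cond], w, records["district"], graph
        )
        table.insert(0, "condition", cond)
        district_tables.append(table)
        print(f"{cond:7s} district prevalence: mean {100 * summary['mean']:.1f}%, "
              f"median {100 * summary['median']:.1f}%, "
              f"range {100 * summary['min']:.1f}-{100 * summary['max']:.1f}%")
    pd.concat(district_tables).to_csv(OUT / "prevalence_by_district.csv", index=False)
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
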