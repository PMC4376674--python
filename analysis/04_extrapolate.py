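"""National extrapolation through the eligibility funnel.

Projects the cohort base case onto the annual US population of medical
inpatients meeting the survey criteria: 14.3M eligible discharges ×51.1%
at VTE risk, of whom 47.5% already receive guideline prophylaxis and 12.2%
of the remainder are contraindicated, leaving ~3.4M eligible-but-
unprotected patients per year.

Finding: full adherence would avert ~16,000 (LMWH) or ~11,000 (UFH) deaths
annually with nine-figure cost savings; each 1% adherence gain averts ~160
(LMWH) or ~110 (UFH) deaths.  The across-hospital IQR of the at-risk share
(44.8–62.2%) scales these totals linearly.

Writes results/national_impact.csv and results/funnel.txt.
"""

from pathlib import Path

from vte_cea.cea import compare
from vte_cea.extrapolation import (
    apply_funnel,
    funnel_rates,
    funnel_report,
    impact_frame,
    iqr_scenario,
    national_impact,
)
from vte_cea.parameters import load_parameters
from vte_cea.tree import build_all_trees, evaluate_tree

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    bundle = load_parameters()
    pop = bundle.population
    n = pop.cohort_size
    OUT.mkdir(exist_ok=True)

    rates = funnel_rates(pop.endorse_counts)
    projection = apply_funnel(
        pop.nis_eligible_total, pop.at_risk_fraction,
        rates["receiving_prophylaxis"], rates["contraindicated"],
    )
    report = funnel_report(pop.endorse_counts, projection)
    (OUT / "funnel.txt").write_text(report + "\n")
    print(report)

    trees = build_all_trees(bundle)
    outcomes = {sid: evaluate_tree(trees[sid], n, sid) for sid in trees}
    cea = {sid: compare(outcomes[sid], outcomes["NONE"]) for sid in ("LMWH", "UFH")}
    impact = {
        sid: national_impact(projection.eligible_unprotected, cea[sid], n)
        for sid in ("LMWH", "UFH")
    }
    frame = impact_frame(impact)

    ranged = iqr_scenario(
        pop.at_risk_iqr, cea, pop, rates["receiving_prophylaxis"], rates["contraindicated"]
    )
    frame["deaths_averted_total_low"] = [ranged[s][0].deaths_averted_total for s in frame["strategy"]]
    frame["deaths_averted_total_high"] = [ranged[s][1].deaths_averted_total for s in frame["strategy"]]
    frame["cost_saved_total_low"] = [ranged[s][0].cost_saved_total for s in frame["strategy"]]
    frame["cost_saved_total_high"] = [ranged[s][1].cost_saved_total for s in frame["strategy"]]
    frame.to_csv(OUT / "national_impact.csv", index=False)

    print()
    for sid in ("LMWH", "UFH"):
        r = impact[sid]
        lo, hi = ranged[sid]
        print(
            f"  {sid}: {r.deaths_averted_total:,.0f} deaths averted/year "
            f"(IQR scenario {lo.deaths_averted_total:,.0f}–{hi.deaths_averted_total:,.0f}), "
            f"${r.cost_saved_total / 1e6:,.0f}M saved; per 1% adherence gain: "
            f"{r.deaths_averted_per_1pct:,.0f} deaths, ${r.cost_saved_per_1pct / 1e6:,.1f}M"
        )
    return frame


if __name__ == "__main__":
    main()
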