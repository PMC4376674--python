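# vte-cea

Decision-tree cost-effectiveness analysis of venous-thromboembolism (VTE)
prophylaxis in acutely ill medical inpatients, from a US healthcare-system
perspective.

Hospitalised medical patients carry a high 30-day risk of deep vein
thrombosis (DVT) and its potentially fatal sequela, pulmonary embolism
(PE).  Anticoagulant prophylaxis — low-molecular-weight heparin (LMWH,
enoxaparin 40 mg qd) or unfractionated heparin (UFH, 5000 IU bid) — reduces
that risk at the price of drug cost and its own adverse events (bleeding,
heparin-induced thrombocytopenia).  This package answers, for a cohort of
10,000 at-risk medical inpatients and for the US inpatient population as a
whole: how many 30-day deaths does prophylaxis avert, and at what net cost?

It is aimed at health-economics and outcomes researchers who want a fully
scripted, testable reimplementation of this classic three-strategy model:
every probability and unit cost lives in one YAML file, every analysis step
is a library call, and an independent patient-level microsimulation
cross-checks the analytic tree evaluation.

## The model

A single-pass 30-day decision tree per strategy *s* ∈ {LMWH, UFH, none}.
Writing `p` for branch probabilities and `c` for unit costs, a cohort of
*N* patients yields expected deaths and costs

    E[deaths_s] = N · Σ_paths  Pr(path) · 1{path ends in death}
    E[cost_s]   = N · ( c_prophylaxis,s + Σ_paths Pr(path) · Σ_nodes∈path c_node )

with mutually exclusive first-level adverse events (bleed `p_bleed,s`, HIT
`p_hit,s`), incident DVT `p_dvt,s` among AE-free patients, a clinical
suspicion → ultrasound cascade deciding DVT treatment, PE risk 0.018 after
treated vs 0.511 after untreated DVT, a sudden-death / suspicion / scan
cascade for PE, false-positive workups at (1 − specificity), and a terminal
underlying-illness death risk of 0.100 for everyone not dying of a modelled
cause.  Strategies are ranked against no prophylaxis by

    ICER = ΔE[cost] / deaths averted            (negative ⇒ cost saving)

with one-way threshold analysis by bisection, probabilistic sensitivity
analysis (beta-distributed probabilities, gamma-distributed costs, 10,000
Monte Carlo iterations) summarised as cost-effectiveness acceptability
curves, and national extrapolation through the eligibility funnel
(14.3M eligible US medical discharges × 51.1% at risk × 52.5% not receiving
prophylaxis × 87.8% without contraindication ≈ 3.4M unprotected patients).

See `docs/methods.md` for assumptions, parameter provenance and numerical
choices.

## Worked example

```python
from vte_cea import load_parameters, build_all_trees, evaluate_tree, compare

bundle = load_parameters()                       # shipped published defaults
trees = build_all_trees(bundle)
outcomes = {s: evaluate_tree(t, 10_000, s) for s, t in trees.items()}
for s in ("NONE", "LMWH", "UFH"):
    o = outcomes[s]
    print(f"{s:>4}: {o.expected_deaths:6.0f} deaths  ${o.expected_total_cost:,.0f}")
r = compare(outcomes["LMWH"], outcomes["NONE"])
print(f"LMWH vs none: {r.deaths_averted:.0f} averted, "
      f"${r.cost_per_death_averted:,.0f}/death averted ({r.dominance})")
```

prints

```
NONE:   1088 deaths  $13,689,806
LMWH:   1040 deaths  $11,306,648
 UFH:   1056 deaths  $12,962,607
LMWH vs none: 48 averted, $-49,784/death averted (dominant)
```

i.e. LMWH prophylaxis averts ~48 of the ~1088 30-day deaths per 10,000
at-risk inpatients **and** saves ~$2.4M — it dominates no prophylaxis, at
roughly $50K saved per death averted (UFH: ~32 averted, ~$23K saved each).

The same pipeline is scripted as numbered drivers that write their tables
under `results/`:

```sh
python analysis/01_basecase.py            # Table of deaths/costs/ICERs
python analysis/02_oneway_thresholds.py   # one-way scans + 14% PE threshold
python analysis/03_psa_ceac.py            # 10,000-iteration PSA + CEAC
python analysis/04_extrapolate.py         # funnel + national annual impact
python analysis/05_microsim_validation.py # 10^6-patient cross-check
```

or interactively via the CLI (`vte-cea basecase`, `vte-cea psa`,
`vte-cea extrapolate --iqr`, `vte-cea threshold --parameter
shared.p_pe_given_untreated_dvt --low 1e-6 --high 0.511`, ...).

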