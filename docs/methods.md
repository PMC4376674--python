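# Methods

## Model structure

The model is a one-admission, 30-day decision tree evaluated in expectation
for a cohort (default 10,000) of acutely ill medical inpatients at
guideline-defined VTE risk, under three strategies: enoxaparin 40 mg once
daily for 7 days (LMWH), unfractionated heparin 5000 IU twice daily for 7
days (UFH), and no prophylaxis.  The time horizon is 30 days, so no
discounting is applied; costs are additive along a path and expressed in
2013 US$.

Per strategy the tree branches as follows.

1. **Prophylaxis adverse events.**  Bleed (`p_bleed`), HIT (`p_hit`) or
   neither, mutually exclusive.  Bleeds are major with probability 0.185
   (cost $10,717, case fatality 0.148) else minor ($5,466, non-fatal); HIT
   is symptomatic with probability 0.543 ($14,032, case fatality 0.098)
   else asymptomatic ($1,064, non-fatal).  AE survivors face no further
   VTE risk — a deliberate simplification inherited from the source model.
2. **DVT.**  AE-free patients develop DVT with the strategy-specific
   `p_dvt` (0.055 / 0.066 / 0.142).  DVT is clinically suspected with
   sensitivity 0.657 (diagnosis cost $449) and confirmed by ultrasound with
   sensitivity 0.960; confirmed DVT is treated ($10,758) with its own
   bleed/HIT risks (0.083 / 0.012, same consequence sub-trees, death cause
   recorded as a treatment AE) and a residual "breakthrough" PE risk of
   0.018.  Unsuspected or ultrasound-negative DVT remains untreated with PE
   risk 0.511.
3. **False-positive DVT workup.**  Patients without DVT are falsely
   suspected with probability 1 − 0.869 (diagnosis cost) and falsely
   ultrasound-positive with probability 1 − 0.962, in which case they are
   anticoagulated (treatment cost and treatment-AE risk, no PE risk).
4. **PE.**  Any PE is immediately fatal with probability 0.100.  Survivors
   are clinically suspected with sensitivity 0.291 (diagnosis cost $582)
   and confirmed by the averaged CT/V-Q scan with sensitivity 0.585
   (treatment cost $19,032).  Among patients whose PE did not occur, a
   false-positive PE workup runs at (1 − 0.910) suspicion and (1 − 0.932)
   scan specificity; falsely treated patients face the anticoagulation
   fatality 0.003.  This false-positive arm is applied within the DVT
   pathway (DVT patients whose PE did not materialise); applying it to the
   entire cohort would add ≈$1M+ to every arm and is incompatible with the
   base-case cost calibration (below).
5. **Underlying illness.**  Every patient not dying of a modelled cause
   faces a terminal, independent death risk of 0.100 ("underlying
   illness"), applied to adverse-event survivors and false-positive
   patients alike.

**PE case fatality is keyed to DVT-treatment status, not to the PE
diagnosis.**  The diagnostic cascade decides *costs* (who gets the PE
diagnosis and treatment bills); *fatality* of every non-sudden-death PE
path is 0.015 when the antecedent DVT was treated (breakthrough PE on
anticoagulation) and 0.260 when it was not.  This is the one genuinely
open reconstruction choice in the model, and it is resolved by
calibration: the alternative reading (fatality 0.015 only for
scan-confirmed PE) reproduces base-case costs but under-produces deaths
averted by ~7% and, decisively, cannot reproduce the published
effectiveness threshold.  Under the adopted reading the model reproduces,
with no fitted quantities, (a) all six base-case deaths/costs within 0.35%,
(b) the 0.5%/0.3% death-rate reductions, and (c) the threshold behaviour:
UFH's deaths averted cross zero at p(PE | untreated DVT) = 0.140, matching
the published 14% — an independent corroboration, since that crossing is
determined by the balance of UFH's AE mortality against its VTE prevention.

### Calibration and residuals

The tree topology was reconstructed from the narrative description of the
source model; the published base-case table is used as the calibration
target with a ±2% acceptance band.  Current residuals at the shipped
defaults: deaths 1087.8 / 1039.9 / 1055.8 (published 1087 / 1040 / 1057),
total costs within +0.002% / −0.03% / +0.34%.  The UFH-specific residual
(−1.3 deaths, +$45K) compounds in UFH deaths averted (32.0 vs ≈30.3
implied) and hence the UFH savings-per-death-averted ratio (−$22.7K vs
−$25.7K published); no narrative-compatible topology variant was found that
removes it without breaking the (much tighter) cost and threshold matches.
National-extrapolation figures inherit the deaths-averted residual
(≈ +1.6% for LMWH, +5.6% for UFH).

## Parameters

All inputs ship in `src/vte_cea/data/params_paper.yaml`, organised to be
diffed line-by-line against the published tables: per-strategy 30-day
probabilities of DVT/bleed/HIT and the 7-day course cost ($380 LMWH, $236
UFH, $0 none); shared consequence, treatment, natural-history and
diagnostic probabilities; unit costs in 2013 US$; and the population
constants (survey funnel counts 9257 → 5196 → 2720 → 1292, 331
contraindicated; 14.3M eligible national discharges; at-risk fraction
0.511 with across-hospital IQR 0.448–0.622).  The averaged-scan rows must
equal the arithmetic mean of the CT and V/Q rows; the loader asserts this
rather than assuming it.  A user config overrides any subset of keys;
everything else falls back to the shipped values, and validation reports
every violated invariant by parameter name.

## Sensitivity analysis

**One-way scans** rebuild the full tree at each grid point.  Threshold
finding bisects a named, monotone criterion (monotonicity is checked on a
coarse grid and non-monotone configurations are refused, never silently
answered).  The shipped criteria are cost-saving and dominance
(cost-saving *and* life-saving), per strategy or jointly.  The published
threshold statement corresponds to the joint-dominance criterion: below
p(PE | untreated DVT) ≈ 0.14 the UFH strategy still saves money but no
longer saves lives.

**PSA.**  Probabilities are drawn from beta distributions parameterised by
an effective sample size (α = p·n, β = (1−p)·n), costs from gamma
distributions parameterised by a coefficient of variation (shape = 1/cv²,
scale = mean·cv²); draws are independent across parameters, and structural
zeros (HIT without heparin) are never sampled.  The CT and V/Q scan rows
are sampled and their mean recomputed, preserving the averaging invariant.
The source publication does not state spreads, so defaults are explicit
package choices: effective sample size 400 for the per-strategy
efficacy/safety rows (the scale of the randomized-trial arms they derive
from), 150 for the shared clinical probabilities (typical of the cohort
studies cited), and cv = 0.25 for costs.  Percentile summaries are
therefore *qualitative* reproductions of the published Monte Carlo rows
(ordering low < base < high), not numeric targets.  Reproducibility: one
master seed spawns one deterministic substream per iteration, so results
are independent of evaluation order.

**CEAC.**  At each willingness-to-pay λ ($ per death averted) the accepted
strategy of an iteration maximises λ·(deaths averted) − (incremental cost)
relative to no prophylaxis; ties go to the cheaper strategy.  Under the
default spreads LMWH is preferred in >70% of iterations at every λ.

## Extrapolation

The funnel applies, to the 14.3M eligible annual US medical discharges, the
weighted at-risk fraction 0.511 (the unweighted survey ratio 52.3% is also
available in config), the exact survey ratios 1292/2720 receiving
prophylaxis and 331/2720 contraindicated, yielding ≈3.37M eligible but
unprotected patients.  National deaths averted = eligible × the unrounded
cohort deaths-averted rate; savings = deaths averted × |savings per death
averted|; per-1%-adherence figures are totals/100.  All arithmetic is
unrounded (display layers round); every impact quantity is linear in the
at-risk fraction, so the IQR scenario simply reruns the chain at the two
endpoints.  A published-text inconsistency is preserved rather than fixed:
the running text quotes ≈$8M and ≈$2.6M as "total" savings where its own
table shows those as the per-1% figures ($803.9M and $262.3M totals); this
package follows the table.

## Synthetic data

Two generators, both pure functions of their seed:

* **Patient-level microsimulation** walks individual patients through the
  strategy tree, sampling each branching with one uniform per patient.
  It shares no arithmetic with the recursive expectation and serves as its
  oracle: at 10⁶ patients per strategy, empirical death rates and mean
  costs agree with the analytic values within 3 standard errors (z-scores
  ≈ ±0.5 in the shipped validation run).
* **Synthetic admissions** draw discharge-like records (truncated-normal
  age around 65 ± 15 y, geometric length of stay with mean 5 d, 43.9%
  operating-room fraction mirroring the survey, independent Bernoulli
  risk/prophylaxis/contraindication flags) to exercise the eligibility
  filters end to end.  Age ≥ 40 and stay ≥ 2 days are inclusive thresholds.
  The generator emulates only what the funnel conditions on — marginal
  fractions and thresholds — and deliberately not hospital clustering,
  survey weighting, ICD-9 coding or correlated comorbidity; passing tests
  certify the filter logic, not demographic realism.

## Numerical choices and limitations

* Branch probabilities at every internal node must sum to 1 within 1e-12;
  path enumeration must conserve mass within 1e-10 and agree with the
  recursive evaluation within 1e-9 relative — both are enforced, giving a
  dual-route check on every evaluation.
* Identical sub-trees are shared and the recursive evaluation memoises on
  node identity, making a full three-strategy evaluation ~0.1 ms and a
  10,000-iteration PSA a few seconds on one core.
* Deaths and dollars are carried unrounded end to end; integer deaths and
  whole-dollar tables are produced only at the display layer.
* The model is a 30-day single pass: no recurrence, no long-term sequelae
  (post-thrombotic syndrome, chronic thromboembolic pulmonary
  hypertension), no QALY weighting, and one admission equals one exposure
  when annualising.  Parameter correlations are not modelled in the PSA.
* The reconstruction residuals quantified above are the honest accuracy
  limit of rebuilding the tree from prose; they are documented rather than
  absorbed into parameter adjustments.
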