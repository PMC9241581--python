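# Methods

This note records the model, its assumptions, and the design choices made
where the published description of the evaluation leaves the implementation
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model structure

A cohort of newly diagnosed advanced *EGFR*-mutated NSCLC patients (start
age 71.4 years UK, 61.6 China) moves weekly between three exclusive states:
progression-free (PF), progressed disease (PD) and death. The horizon is
1043 weeks (20 years), which is "lifetime" for this population: under the
reference OS curve fewer than 10⁻³ of the cohort is alive at the horizon.
No half-cycle correction is applied — with one-week cycles the correction
is far below every other source of error. State membership is evaluated at
cycle start.

Time conventions: the Weibull parameters are per *month* (the only unit
under which the printed parameters give clinically sensible curves: median
reference PFS ≈ 5.6 months, mean reference OS ≈ 33.5 months, consistent
with the published reference-arm life-years of ≈2.6). Weekly cycles
convert as t_months = weeks × 7/30.4375; a year is 365.25/7 ≈ 52.18 weeks.

## Survival and transitions

Reference-arm PFS and OS are Weibull, S(t) = exp(−λt^γ). Every comparator
shares γ and multiplies λ by its hazard ratio versus the reference
chemotherapy, which is exact proportional hazards for shared shape.
Per-cycle exit probabilities use the closed form
1 − exp(−λ(t₁^γ − t₀^γ)), which never underflows at late cycles.

The transition structure converts the two survival curves into state
transitions:

* PF exits follow the PFS curve, floored at the age-specific weekly
  background mortality 1 − (1−q)^(1/52.18) from the life table (integer-age
  lookup, clamped above the table's last row); that floor is also the
  PF→death flow.
* Total deaths track 1 − S_OS; the PD→death probability is calibrated each
  cycle as the residual deaths demanded by the OS curve, clipped to [0,1].
  Clipping on more than 5% of cycles (possible only for contradictory
  curve pairs, e.g. much slower progression with much faster death than
  the reference) is recorded as a trace warning.

Parametric fitting of reconstructed patient-level data supports the five
standard families (exponential, Weibull, Gompertz, log-logistic,
log-normal) by right-censored maximum likelihood via lifelines; Gompertz
(hazard a·e^{bt}) is implemented on lifelines' parametric-fitter machinery
since the library ships none. Selection minimises BIC, ties broken by AIC
then by the conventional family order.

## Costs

All costs are 2019 GBP (the China set is converted at 1 GBP = 8.78 CNY;
the constant is carried as metadata only). The published per-cycle
acquisition/administration/management costs are interpreted as *per weekly
model cycle while applicable*. This reading was fixed by reconciling the
input table against the published totals before any calibration: e.g.
erlotinib+bevacizumab's UK total (~£106k) is reproducible only if the
bevacizumab component (£878 = combination row minus erlotinib row) accrues
weekly until progression, and the same check holds for osimertinib
(£1346/week × ≈90 PF weeks) and gefitinib (£66/week).

Accrual rules:

* Oral TKI components: weekly while in PF (treatment until progression or
  death), plus the TKI administration cost (UK only).
* Chemotherapy infusion components: weekly for at most four 3-week cycles
  (12 weeks), in the pure chemotherapy arms **and** in the
  gefitinib+pemetrexed / gefitinib+PbCT combinations, following the blanket
  4-cycle rule of the source; monoclonal-antibody components (bevacizumab,
  cetuximab) accrue until progression. Active infusion weeks also carry the
  infusion administration cost.
* Combination acquisition rows are published as a single figure; the
  fixtures split them as oral = the TKI's own row and infusion =
  combination − oral, with the gamma scale re-derived (shape 96.04 kept) so
  the distribution mean matches the component. The PSA consequently samples
  the two components independently.
* Disease-management costs accrue by occupancy (PF and PD rates).
* Second-line pathways apply to the uptake fraction (61.0% UK, 52.8%
  China) of PD entrants by time since progression: TKI-based arms receive
  pemetrexed+platinum (≤12 weeks) then docetaxel (≤12 weeks) then best
  supportive care; chemotherapy and gefitinib-combination arms receive
  docetaxel (≤12 weeks) then BSC. Non-uptake patients receive BSC from
  progression; BSC applies only after active lines end, never concurrently.
  Implementation: PD entry cohorts share the calibrated per-cycle PD death
  probability, so tenure-specific costs reduce to BSC × PD occupancy plus a
  short convolution over the active-phase excess (O(K·phase length)).
* Terminal care is a one-off per new death, from PF or PD alike.
* SAE management costs and disutilities are applied once, at model entry,
  as incidence-weighted one-offs — matching the per-event costing and the
  single QALY-loss figure of the source.

QALYs accrue as (u_PF·PF + u_PD·PD)/52.18 per week; life-years likewise
with unit weights. Cycle-k quantities are discounted by (1+r)^(−k/52.18),
r = 3.5%/yr UK, 5%/yr China.

## Parameter files and the transcription audit

Every uncertain scalar is stored as base value, deterministic range
(defaulting to ±20% where the source prints none) and PSA distribution. At
load time the distribution's central value (gamma/beta/normal mean,
lognormal median) is audited against the base value. The tolerance is 2%
or one unit of the printed resolution, whichever is larger — the printed
tables themselves round a handful of small costs by more than 2% (e.g. a
£4 SAE cost whose gamma mean is 4.8). Uniform distributions are exempt:
the published discount-rate uniforms are deliberately not centred on the
base rate.

Known fixture limitations, all overridable in the YAML:

* Per-arm SAE incidences: only five gefitinib+PbCT vs gefitinib pairs are
  published in the main text; the remaining entries are placeholders drawn
  from the pivotal trials' grade-3/4 safety profiles. SAE disutilities are
  literature-typical placeholders. They move totals by at most a few
  hundred pounds and ~0.07 QALYs.
* Life tables are synthetic Gompertz–Makeham tables
  (q(age) = 1 − exp(−(a + c·e^{b·age})), calibrated to ≈2% annual mortality
  at the UK start age), not national tables.
* China dacomitinib uses the printed list-derived price; the original
  evaluation additionally applied a patient-assistance-program adjustment
  (supplementary detail), so its modelled China total is roughly double
  the published one. The arm is strictly dominated under either price.

With these fixtures the deterministic model reproduces the published
per-arm discounted totals mostly within ±5–10% and all the published
direction-level findings (QALY ranking, acceptability-curve winners); it
does not reproduce the absolute totals exactly, and on the package's own
fixture the cheapest-arm ordering of gefitinib vs reference chemotherapy
(a £500 margin in the published table) can flip. Exact incremental
arithmetic is therefore checked against the published cost/QALY table
itself, which ships with the package.

## Sensitivity analyses

*One-way:* each scalar parameter in turn at its low/high bound, reporting
the ICER of a chosen comparison (default: gefitinib+PbCT vs reference
chemotherapy, the comparison discussed in the source). The reference
Weibull scale/shape pairs are excluded from the default tornado set —
they are correlated, jointly sampled pair parameters for which independent
one-at-a-time variation is not meaningful — but remain addressable
explicitly.

*Scenarios:* (1) updated osimertinib OS data — the updated hazard ratio is
not printed in the main text; a stand-in of 0.60 (vs base 0.65) is used;
(2) alternative utilities — PD utility 0.473 as printed, PF stand-ins
0.653 (UK) / 0.804 (China) from the cited utility studies; (3) UK list
(BNF) prices — approximate list prices replacing procurement prices for
the eMIT-sourced drugs; (4) second-line osimertinib for the 60% of
first/second-generation-TKI patients assumed T790M-positive (10 months of
second-line osimertinib; the rest receive 4 cycles of pemetrexed-based
chemotherapy). All scenario constants are module-level and editable.

*Probabilistic:* second-order Monte Carlo. Gamma for costs, lognormal for
hazard ratios, beta for utilities/disutilities/probabilities, uniform for
the discount rate (U(0, 0.06) UK; U(0, 0.08) China). Each Weibull
(ln λ, ln γ) pair is drawn jointly through a Cholesky factor whose marginal
SDs are back-solved from the printed 95% intervals and whose correlation
defaults to −0.5 (the typical negative scale–shape correlation of Weibull
fits; configurable). The life table is held fixed. A master seed spawns
per-iteration integer substream seeds, recorded in the output for replay.
CEACs report, per willingness-to-pay threshold, the fraction of iterations
in which each arm attains the maximum net monetary benefit; exact ties
split equally.

The CLI default is 5000 iterations. The test suite exercises the PSA at
150 iterations per country for the acceptability-curve checks and 40–240
iterations for calibration properties — the direction-level quantities it
asserts (which arm wins at a threshold, probabilities summing to one) are
stable well below these sizes.

## Synthetic data

The generators emulate the statistical structures the pipeline consumes:
right-censored Weibull event times with uniform censoring (the censoring
window is solved numerically so the expected censored fraction hits the
target — the simplest mechanism consistent with administrative censoring),
Gompertz–Makeham life tables, uniform random cost-QALY planes, and full
randomized input sets with the same fixed-CV gamma / beta / lognormal
distribution families as the real fixtures. They do not emulate
trial-specific recruitment or dropout, informative censoring, or any
correlation between efficacy and safety across arms — so passing tests
demonstrate correctness of the machinery under the model's own assumptions,
not robustness to violations of them.

## Numerical choices

* Transition probabilities in log space (no survival-ratio underflow).
* PD-survival products clipped at 10⁻³⁰⁰ before taking logs; calibration
  clipping tracked and surfaced as a warning above 5% of cycles.
* Frontier ties: exactly equal (cost, QALY) pairs keep the
  first-by-input-order arm, the duplicate is classified dominated;
  extended dominance uses a strict ICER-violation test so exactly
  collinear points stay on the frontier (no convex combination strictly
  improves on them). Dominance is weak (no worse on both axes, strictly
  better on one).
* ICERs with a zero QALY difference are flagged degenerate, not returned
  as numbers; dominance comparisons carry the forced ratio for reporting.
* All stochastic components take explicit integer seeds or Generators and
  are bitwise reproducible.

## Limitations

Individual-level simulation (and hence time-to-discontinuation separate
from PFS), value-of-information analysis, currency/CPI adjustment and
Kaplan–Meier curve digitization are out of scope. The network meta-analysis
hazard ratios are consumed as inputs; their internal consistency is not
re-assessed here.
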