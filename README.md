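# nsclc-cea

Cost-effectiveness modelling of the twelve first-line treatment strategies
for advanced *EGFR*-mutated non-small-cell lung cancer — six EGFR tyrosine
kinase inhibitors (osimertinib, dacomitinib, afatinib, erlotinib, gefitinib,
icotinib), four combinations (afatinib+cetuximab, erlotinib+bevacizumab,
gefitinib+pemetrexed, gefitinib+pemetrexed-based chemotherapy) and two
chemotherapies — from the perspectives of the UK NHS and the Chinese
health-care system.

The package is aimed at health-economics analysts who want a tested,
scriptable implementation of the full decision-model pipeline:

* **Survival extrapolation.** Reference-arm PFS and OS follow
  S(t) = exp(−λt^γ) (t in months); comparator arms share γ and scale λ by
  the network-meta-analysis hazard ratio, which is exact proportional
  hazards. Right-censored MLE fitting of the five standard parametric
  families with BIC/AIC selection is included (`fit_parametric`,
  `select_model`).
* **Markov cohort model.** Weekly cycles over three states
  (progression-free, progressed, dead) for a lifetime (20-year) horizon.
  PF tracks the PFS curve with an age-specific background-mortality floor
  from a life table; the PD death probability is calibrated each cycle so
  cumulative deaths track the OS curve. Costs (acquisition,
  administration, disease management, second/third-line pathways, best
  supportive care, terminal care, adverse events) and utility-weighted
  QALYs accrue per cycle and are discounted at 3.5%/yr (UK) or 5%/yr
  (China).
* **Incremental analysis.** ICERs, strict and extended dominance, the
  cost-effectiveness frontier with sequential ICERs, and net monetary
  benefit NMB(λ) = λ·QALY − cost.
* **Uncertainty.** One-way sensitivity analysis with tornado ranking,
  four scenario analyses, and probabilistic sensitivity analysis
  (gamma costs, lognormal hazard ratios, beta utilities/probabilities,
  jointly sampled Weibull parameters) with cost-effectiveness
  acceptability curves.
* **Synthetic data.** Seeded generators for censored Weibull survival
  data, Gompertz–Makeham life tables, random cost-QALY planes and full
  randomized input sets, so every stage is testable offline.

Parameter sets transcribed from the published input tables ship with the
package (`inputs` for the UK and China, including per-arm serious-adverse-
event profiles and synthetic life tables), as does the published base-case
cost/QALY table used for cross-checking the incremental analysis.

## Worked example

```python
from nsclc_cea import load_packaged_inputs, run_all, build_frontier

inputs = load_packaged_inputs("uk")          # 11 arms (icotinib is China-only)
results = run_all(inputs)                    # deterministic base case
front = build_frontier(results)
print(front.to_frame(reference="pfct").head(4).round(3))
```

```
         arm       cost   qaly     ly  icer_vs_reference  sequential_icer classification
0       pfct  25480.257  0.740  2.601                NaN              NaN    on_frontier
1  gefitinib  26087.788  1.130  2.566           1555.928         1555.928    on_frontier
2       pbct  27591.958  0.829  2.422          23640.594              NaN      dominated
3  erlotinib  28845.260  1.177  2.549           7698.329              NaN extended_dominated
```

Reading the output: gefitinib buys 0.390 extra QALYs over the reference
chemotherapy for ~£600 more (ICER ≈ £1.6k/QALY), erlotinib is excluded by
extended dominance, and the frontier continues through
gefitinib+pemetrexed-based chemotherapy to osimertinib. With the packaged
fixtures osimertinib and gefitinib+PbCT gain the most QALYs (1.76 and 1.69
in the UK) and the two chemotherapies the least, and in probabilistic
analysis gefitinib is most likely cost-effective at the lower
willingness-to-pay threshold (£20,000/QALY UK, £8,000/QALY China) while
gefitinib+PbCT takes over at the higher threshold (£50,000 / £24,000) —
the same qualitative picture as the published evaluation.

A command-line interface mirrors the library:

```bash
nsclc-cea run --country uk --outdir out/          # base case + frontier CSVs
nsclc-cea dsa --country china --comparison gefitinib_pbct,pfct --outdir out/
nsclc-cea psa --country uk --n 5000 --seed 2022 --outdir out/
nsclc-cea fit-survival --data pfs_data.csv --outdir out/
```

## Layout

```
src/nsclc_cea/params.py       input types, validation, YAML/CSV I/O
src/nsclc_cea/survival.py     Weibull curves, HR algebra, parametric MLE
src/nsclc_cea/markov.py       weekly cohort trace + cost/QALY accrual
src/nsclc_cea/frontier.py     ICERs, dominance, frontier, NMB
src/nsclc_cea/sensitivity.py  one-way DSA, scenarios, PSA, CEAC
src/nsclc_cea/synthetic.py    seeded generators for all input structures
src/nsclc_cea/data/           UK/China parameter sets + published totals
docs/methods.md               modelling assumptions and design choices
```
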