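# cllcea

Lifetime cost-effectiveness modelling of first-line therapy for older Chinese
patients with chronic lymphocytic leukemia (CLL).

## The problem

Chinese guidelines allow two first-line strategies for previously untreated
CLL patients aged 65+ without del(17p)/TP53 mutation: continuous oral
ibrutinib (IB), or six cycles of intravenous bendamustine + rituximab (BE+RI)
followed by oral lenalidomide (LE) maintenance. After Chinese insurance-price
negotiations, IB costs ≈ $2,360/month — far below Western prices — so the
usual finding that IB is not cost-effective needs re-examination from the
Chinese payer perspective.

`cllcea` implements that comparison as a tested, reusable decision-modelling
package for health economists:

* **Survival extrapolation** — six parametric families (exponential, Weibull,
  Gompertz, gamma, lognormal, loglogistic) on a monthly axis, with
  right-censored MLE fitting and AIC/BIC model selection.
* **Pseudo-IPD reconstruction** — the Guyot-style interval algorithm that
  rebuilds approximate individual patient data from digitized Kaplan–Meier
  coordinates and number-at-risk tables, validated by KM round trips.
* **Semi-Markov cohort engine** — states EFS → TF (transient) → PF
  (expanded into 2nd line, 3rd line, allo-HSCT, BSC) → death, monthly cycles
  for 4 years then annual cycles to 10 years, line-specific PFS/OS clocks,
  census-style background mortality, 5%/year discounting.
* **Costing and utilities** — drug acquisition, chemo administration,
  hospitalization, supportive drugs, severe adverse events, follow-up,
  BSC, transplant and end-of-life costs (2022 USD); state utilities with
  one-off SAE disutilities.
* **Economics** — total costs/QALYs per strategy, incremental
  cost-effectiveness ratio ICER = ΔC/ΔE, dominance classification, net
  monetary benefit NMB = λ·E − C at the Chinese willingness-to-pay threshold
  λ = $38,223.34/QALY (3× GDP per capita).
* **Sensitivity analysis** — one-way tornado over the published ranges, and a
  1000-draw probabilistic sensitivity analysis (gamma costs, beta
  utilities/probabilities/risks, normal body surface area) with
  cost-effectiveness plane and acceptability-curve outputs.
* **Synthetic data** — seeded cohort simulation, digitization emulation and
  life-table fixtures so the whole pipeline is testable offline.

## Worked example

```python
>>> import cllcea
>>> inputs = cllcea.default_inputs()          # the packaged model definition
>>> res = cllcea.base_case(inputs)            # BE+RI compared against IB
>>> round(res.qaly_b, 2), round(res.qaly_a, 2)
(4.46, 3.74)
>>> round(res.cost_b, 2), round(res.cost_a, 2)
(185535.97, 281839.42)
>>> round(res.delta_cost, 2), round(res.delta_qalys, 4), round(res.icer, 2)
(96303.45, -0.7217, -133431.06)
>>> res.label
'dominated'
```

First-line IB yields 4.46 discounted QALYs for $185,536 per patient over ten
years; BE+RI yields 3.74 QALYs for $281,839. BE+RI is therefore *dominated*:
it costs $96,303 more and loses 0.72 QALYs (a negative ICER of
−$133,431/QALY means money is spent to lose health relative to IB). The
same comparison is available from the shell:

```bash
cllcea base-case --out results/       # Table of QALYs + cost categories
cllcea dsa --out results/             # tornado.csv (top-15 one-way swings)
cllcea psa --out results/ --n-draws 1000 --seed 1
```

The packaged tornado is led by the lenalidomide monthly price, the ibrutinib
monthly price and the discount rate, and every one-way ICER stays negative;
in the seeded 1000-draw PSA, 100% of draws fall in the quadrant where IB is
cheaper and more effective, so the acceptability curve sits at 100% for any
non-negative willingness-to-pay.

All inputs live in a YAML model definition
(`src/cllcea/data/default_model.yaml`); pass `--model your_model.yaml` to any
subcommand to run a modified scenario.

## Layout

```
src/cllcea/
  survival.py     parametric families, transition probabilities, MLE, AIC/BIC
  ipd.py          digitized-curve types, Guyot reconstruction, KM estimation
  markov.py       cycle plan, life table, semi-Markov cohort engine
  costing.py      cost/utility accrual rules, CPI adjustment
  economics.py    ICER, dominance, net monetary benefit
  sensitivity.py  parameter specs, tornado DSA, Monte-Carlo PSA, CEAC
  synthetic.py    seeded fixtures: cohorts, digitizations, life tables
  config.py       model definition, YAML round trip
  cli.py          `cllcea` console entry point
docs/methods.md   modelling assumptions, parameters and limitations
```
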