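# Methods

## Decision problem and model structure

The package compares two first-line strategies for previously untreated CLL
patients aged 65+ without del(17p)/TP53, from the Chinese payer perspective:

* **IB arm** — oral ibrutinib until progression; on failure, zanubrutinib
  (2nd line), then orelabrutinib (3rd line).
* **BE+RI arm** — six 28-day cycles of intravenous bendamustine + rituximab
  with hospitalization and supportive medication, then oral lenalidomide
  maintenance (5/10/15 mg escalation over cycle 7, cycles 8–12, and
  thereafter) until progression; on failure, ibrutinib (2nd line), then
  zanubrutinib (3rd line).

After the last drug line, progression leads to allogeneic stem-cell
transplant; progression after transplant leads entirely to best supportive
care (BSC). After every drug line a fixed fraction of progressors moves to
BSC instead of the next line (0.15 after first line, 0.19 after later lines).

The classic four-state diagram (event-free survival EFS, transient treatment
failure TF, post-treatment failure PF, death) is expanded: PF is split into
2nd line / 3rd line / transplant / BSC sub-states so that each line's fitted
progression-free (PFS) and overall survival (OS) curves apply from *line
entry*. Line clocks are realised with tunnel compartments keyed by entry
cycle, making the engine semi-Markov. Cycles are monthly for the first 48
months and annual thereafter to a 10-year horizon (54 cycles); annual
transition probabilities are taken from survival ratios at the yearly
boundaries, not by compounding monthly values, so they remain exact under
the parametric curves.

Within a line, per-cycle probabilities are

* `die = max(1 − S_os(τ+δ)/S_os(τ), background)` — the background
  (life-table) floor applies in post-failure states by default
  (`background_mortality_scope="pf_only"`; an `all_alive` switch exists);
* `fail = max(0, 1 − S_pfs(τ+δ)/S_pfs(τ) − die)` — PFS events net of death,
  since a PFS curve counts deaths as events;
* `stay = 1 − fail − die` (a negative residual raises a model error rather
  than being clamped silently).

TF lasts exactly one cycle and cannot die during it; in the annual phase
this means a progressor spends one year in TF, a granularity artefact of the
published cycle plan. BSC exits only to death, at the life-table rate.

The transplant sub-state uses configurable piecewise-constant monthly
probabilities (defaults: relapse 0.02/month for 24 months then 0.005;
non-relapse mortality 0.015/month for 12 months then 0.003). These defaults
are assumptions — published cumulative-incidence digitizations are not
reproduced here — and transplant occupancy is a fraction of a percent of the
cohort, so results are insensitive to them.

The third-line agent in the IB arm (orelabrutinib) has no published survival
curves; it borrows the zanubrutinib PFS/OS shapes, with its objective
response rate (0.91) acting as a one-way-sensitivity lever that scales the
progression hazard by `0.91 / ORR`.

## Survival inputs

Fitted parametric curves (monthly axis), as shipped in the default model
definition:

| curve | family | parameters |
|---|---|---|
| IB 1L PFS | exponential | rate 0.00592451 |
| IB 1L OS | exponential | rate 0.00368296 |
| BE+RI 1L PFS | Gompertz | shape 0.02325928, rate 0.00943535 |
| BE+RI 1L OS | exponential | rate 0.00332761 |
| IB 2L PFS | gamma | shape 1.1802239, rate 0.0191373 |
| IB 2L OS | exponential | rate 0.0100394 (see below) |
| ZB 2L/3L PFS | Gompertz | shape 0.0341335, rate 0.00268049 |
| ZB 2L/3L OS | lognormal | meanlog 1.59, sdlog 164.93 (see below) |

Two published parameter values deserve comment:

* **Relapsed-line IB OS.** The source table prints an exponential rate of
  0.00100394/month, i.e. ≈ 1.2% annual mortality (median OS ≈ 57 years) for
  relapsed CLL patients in their seventies — inconsistent with the trial the
  curve was fitted to, whose median OS of ≈ 67 months pins the rate at
  ≈ 0.010. The package defaults to 0.0100394, reading the printed figure as
  a one-decimal slip; the literal value can be restored in the YAML config.
* **ZB OS lognormal.** The printed sdlog of 164.93 produces a degenerate
  curve: survival drops to ≈ 0.50 within the first month of the line and is
  essentially flat afterwards (all later mortality in that line then comes
  from the life-table floor). It is implemented as printed, with an
  `options.zb_os_override` hook for a replacement distribution.

The Gompertz family uses the proportional-hazards form
`S(t) = exp(−(rate/shape)(e^{shape·t} − 1))`, chosen because the BE+RI PFS
parameters then reproduce the source trial's ≈ 74% two-year PFS; the
loglogistic uses `S(t) = 1/(1+(t/scale)^shape)`, the lognormal
meanlog/sdlog of log-time, the gamma shape/rate on time, and the Weibull
`S(t) = exp(−(rate·t)^shape)`. Time is months throughout: the printed
exponential rates reproduce the trials' two-year survival only on a monthly
axis.

## Accrual conventions

Costs (2022 USD) and QALYs accrue at **cycle start** with the cycle-start
discount factor `(1.05)^(−t/12)`; there is no half-cycle correction (a
config switch exists). End-of-life cost ($12,455.19) is charged to the
fraction dying in a cycle; the transplant lump sum ($59,621.17) on entry.
Routine follow-up visits ($48.80) occur every 3 months in years 1–2, every
6 months in years 3–5, then annually, for every alive non-BSC state. BSC
costs $299.95/month.

Drug acquisition uses the printed per-month prices (a "month" = one 28-day
dosing block; the per-mg list prices are carried in the config for
reference but per-mg × regimen × BSA does not reconcile with the printed
monthly figures, so the monthly figures are canonical and body surface area
is economically inert). Lenalidomide's 5/10/15 mg escalation is priced at
1/3, 2/3 and the full monthly price. Chemo months 1–6 add supportive drugs
($2,703.17) and hospitalization ($1,454.95) per cycle plus three infusion
($0.22) and three allocation ($0.90) fees.

Severe (grade ≥3) adverse events — neutropenia, thrombocytopenia, febrile
neutropenia, hypertension — are charged once, in the first month of
first-line treatment, as expected cost Σ risk×unit-cost and expected
one-month disutility Σ risk×disutility. The hypertension-affected fraction
additionally accrues $129.48/year of outpatient cost for the rest of its
lifetime (the published rule states no duration; lifetime accrual is the
package's choice).

Utilities: EFS 0.71 (oral) / 0.67 (intravenous chemo months 1–6); the
transient TF stage after first-line failure 0.66 ("progression after
first-line therapy"); all relapsed-line states, transplant and BSC 0.42;
death 0. Assigning 0.66 to the entire second-line state instead is the main
alternative reading of the published utility table; it raises the BE+RI
total by ≈ 0.45 QALYs and is not used.

Cost categories — first-line (drug + chemo delivery), subsequent-line
drugs, adverse events, other (follow-up, BSC, transplant, end-of-life) —
partition the total exactly.

The cohort enters at age 70 (trial median 70–71) for life-table lookup. The
packaged life table is a synthetic Gompertz–Makeham profile,
`q(a) = 0.0008 + 0.0115·e^{0.088(a−65)}` for ages 65–100, on the scale of
census-based elderly mortality in China; it is replaceable through the
config, and headline comparisons are therefore checked against tolerance
bands rather than exact equality.

## Sensitivity analysis

One-way analysis re-runs the comparison at each parameter's published low
and high bound (ranges are low–high where printed, else ±25%) and ranks by
ICER swing; the discount rate varies over [0, 0.08]. The PSA draws gamma
distributions for costs (a config switch selects the all-normal variant),
beta for utilities, probabilities and adverse-event risks, and normal for
body surface area; survival parameters and the discount rate stay fixed.
Moment matching sets each distribution's mean to the base value and its
standard deviation to (high − low)/3.92, so the central 95% interval
approximates the one-way range; a beta whose variance is infeasible
collapses to the base value. Draws are joint-independent, seeded through
`numpy.random.default_rng`, and bit-reproducible for a given seed.

## Synthetic-data generator

The generator stands in for the two external data sources the analysis
rests on: digitized trial Kaplan–Meier figures and census mortality. It
simulates seeded cohorts from known parametric truth (event time = min of
event and censoring draws), evaluates the exact KM curve and risk counts on
a reporting grid (default every 3 months to 48 months, mimicking trial
cadence) with optional bounded jitter emulating digitization error, and
builds abridged life tables (flat / aging / zero profiles). What it does
*not* emulate: reader bias in digitization, informative censoring,
inter-trial population differences, and real census age structure — so
green round-trip tests certify the algorithms, not the fidelity of the
original digitizations.

Pseudo-IPD reconstruction allocates integer events and censorings per
risk-table interval (censor times spread uniformly, iterating the censoring
budget until the implied next risk-set size matches; fractional event
counts integerised by largest-remainder rounding so interval totals are
conserved). Beyond the last risk-table time no censoring is assumed until
the last digitized point, where survivors are censored. When a published
total event count is available it is matched by flipping the latest
censoring/event flags.

## Numerical choices and problem sizes

* MLE: L-BFGS-B on log-transformed positive parameters, three starts
  (scale 0.5/1/2 around moment-based initials); non-identifiable input
  (< 2 events) raises rather than returning a degenerate fit.
* Information criteria: AIC = −2ℓ + 2k, BIC = −2ℓ + k·ln n with n = number
  of subjects; selection ties break toward fewer parameters, then
  family-name order.
* Engine conservation is enforced to 1e-9 per cycle; transition-probability
  composition holds to 1e-12; the exponential cohort oracle matches a
  geometric closed form to 1e-6.
* Test problem sizes: parameter-recovery fits use n = 5,000 (5% tolerance),
  the full digitize→reconstruct→fit loop n = 500 (10%), round-trip KM
  checks n = 200 (max deviation < 0.02), and the PSA 1,000 draws — sizes
  chosen so the whole suite and the acceptance script each finish in a few
  minutes on one CPU.

## Known limitations

* Relapsed-line residence is governed by the printed second-line PFS curve
  (mean ≈ 62 months); the resulting subsequent-line drug costs and
  post-failure QALYs in the BE+RI arm exceed the published base-case
  breakdown, whose implementation evidently truncated relapsed-line
  residence in an unreported way. The headline totals and dominance are
  unaffected, but the incremental QALY gain here (≈ 0.72) is smaller than
  the published 1.17.
* The health-CPI series in `CPIAdjuster` is a synthetic approximation used
  only by the optional cost-adjustment helper; all packaged inputs are
  already 2022 USD.
* No individual-level microsimulation, treatment discontinuation beyond the
  trial curves, vial wastage, indirect costs, or >2-strategy frontiers.
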