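survival:
  ib1l_pfs:
    family: exponential
    params:
      rate: 0.00592451
  ib1l_os:
    family: exponential
    params:
      rate: 0.00368296
  beri1l_pfs:
    family: gompertz
    params:
      shape: 0.02325928
      rate: 0.00943535
  beri1l_os:
    family: exponential
    params:
      rate: 0.00332761
  ib2l_pfs:
    family: gamma
    params:
      shape: 1.1802239
      rate: 0.0191373
  ib2l_os:
    family: exponential
    params:
      rate: 0.0100394
  zb_pfs:
    family: gompertz
    params:
      shape: 0.0341335
      rate: 0.00268049
  zb_os:
    family: lognormal
    params:
      meanlog: 1.59
      sdlog: 164.93
costs:
  ib_month: 2360.36
  zb_month: 2940.04
  ob_month: 2995.66
  be_month: 1543.1
  ri_month: 1797.48
  le_month: 5069.89
  ib_mg: 0.2
  zb_mg: 0.33
  ob_mg: 0.71
  be_mg: 8.57
  ri_mg: 3.59
  le_mg: 12.07
  iv_infusion: 0.22
  drug_allocation: 0.9
  supportive_per_cycle: 2703.17
  hospitalization_per_cycle: 1454.95
  sae_neutropenia: 815.1
  sae_thrombocytopenia: 605.63
  sae_febrile_neutropenia: 4516.31
  sae_hypertension: 968.52
  hypertension_outpatient_year: 129.48
  followup_visit: 48.8
  bsc_month: 299.95
  allo_hsct: 59621.17
  end_of_life: 12455.19
utilities:
  efs_oral: 0.71
  efs_iv: 0.67
  pf_after_first_line: 0.66
  relapsed_lines: 0.42
  death: 0.0
  du_neutropenia: 0.163
  du_thrombocytopenia: 0.108
  du_febrile_neutropenia: 0.15
  du_hypertension: 0.195
sae:
  ib:
    neutropenia: 0.15
    thrombocytopenia: 0.0667
    febrile_neutropenia: 0.0167
    hypertension: 0.2944
  beri:
    neutropenia: 0.4034
    thrombocytopenia: 0.1477
    febrile_neutropenia: 0.0739
    hypertension: 0.142
probs:
  orr_ob: 0.91
  bsc_after_first_line: 0.15
  bsc_after_later_lines: 0.19
allo:
  relapse_monthly_early: 0.02
  relapse_monthly_late: 0.005
  relapse_early_months: 24
  nrm_monthly_early: 0.015
  nrm_monthly_late: 0.003
  nrm_early_months: 12
options:
  half_cycle_correction: false
  background_mortality_scope: pf_only
  cost_psa_distribution: gamma
  zb_os_override: null
life_table:
  ages:
  - 65
  - 66
  - 67
  - 68
  - 69
  - 70
  - 71
  - 72
  - 73
  - 74
  - 75
  - 76
  - 77
  - 78
  - 79
  - 80
  - 81
  - 82
  - 83
  - 84
  - 85
  - 86
  - 87
  - 88
  - 89
  - 90
  - 91
  - 92
  - 93
  - 94
  - 95
  - 96
  - 97
  - 98
  - 99
  - 100
  annual_q:
  - 0.0123
  - 0.013357863403324271
  - 0.0145130376744827
  - 0.015774474257460282
  - 0.01715194802276364
  - 0.018656133012880362
  - 0.020298685155420926
  - 0.02209233258488719
  - 0.02405097427297076
  - 0.02618978773166727
  - 0.02852534662379791
  - 0.031075749192301903
  - 0.033860758503498484
  - 0.03690195559106306
  - 0.04022290668743034
  - 0.04384934583849991
  - 0.047809374316725925
  - 0.052133678377842115
  - 0.0568557670486193
  - 0.06201223178827191
  - 0.06764303003562974
  - 0.07379179483928174
  - 0.08050617297001474
  - 0.08783819413558107
  - 0.09584467415883886
  - 0.10458765524349235
  - 0.11413488673905123
  - 0.12456035013045502
  - 0.13594483232050777
  - 0.14837655164748695
  - 0.1619518414889365
  - 0.17677589674888955
  - 0.1929635890130479
  - 0.21064035668855652
  - 0.22994317702606396
  - 0.25102162755626634
bsa: 1.72
discount_rate: 0.05
horizon_years: 10
wtp: 38223.34
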