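# Base-case model parameters for the blood-test-triaged lung cancer screening
# cost-effectiveness model.
#
# Each leaf parameter has:
#   value: base-case value (units in the comment)
#   psa:   sampling distribution for probabilistic sensitivity analysis;
#          omitted -> parameter held fixed across PSA draws.
#          beta: {dist: beta, a: .., b: ..}
#          gamma / normal: {dist: .., sd: ..} moment-matched to (value, sd)
#   dsa:   [min, max] range for one-way deterministic sensitivity analysis;
#          omitted -> parameter excluded from DSA.

epidemiology:
  # probability of underlying lung cancer at the start of screening
  prevalence:
    value: 0.02
    psa: {dist: beta, a: 241.62, b: 11839.38}
    dsa: [0.01, 0.04]
  # share of prevalent cancers that are early stage (I/II)
  prevalence_early:
    value: 0.4107
    psa: {dist: beta, a: 23.0, b: 33.0}
    dsa: [0.25, 0.75]
  # probability an early-stage case outside the LDCT pathway is detected
  # opportunistically through routine care during the screening window
  op_es:
    value: 0.3779
    psa: {dist: beta, a: 19.0, b: 31.2796}
    dsa: [0.0, 1.0]
  # same for late-stage cases
  op_ls:
    value: 0.7208
    psa: {dist: beta, a: 52.0, b: 20.1404}
    dsa: [0.0, 1.0]

accuracy:
  # blood-test sensitivity for early-stage cancer, P(T+|ES)
  sens_es:
    value: 0.5217
    psa: {dist: beta, a: 12.0, b: 11.0}
    dsa: [0.25, 0.75]
  # blood-test sensitivity for late-stage cancer, P(T+|LS)
  sens_ls:
    value: 0.1818
    psa: {dist: beta, a: 6.0, b: 27.0}
    dsa: [0.09, 0.36]
  # blood-test specificity, P(T-|no disease)
  spec:
    value: 0.9038
    psa: {dist: beta, a: 5451.0, b: 580.0}
    dsa: [0.5, 1.0]
  # 6-monthly LDCT programme sensitivity, P(LDCT+|disease)
  ldct_sens:
    value: 1.0
    dsa: [0.75, 0.9]
  # 6-monthly LDCT programme specificity, P(LDCT-|no disease)
  ldct_spec:
    value: 1.0
    dsa: [0.75, 0.9]

costs:
  # GBP per participant for the blood test (kit + nurse administration)
  test_cost:
    value: 106.5
    dsa: [59.0, 201.5]
  # GBP diagnostic (LDCT + imaging) cost, TP and FP pathways
  diag_tp_fp:
    value: 1620.23
    psa: {dist: gamma, sd: 29.90}
  # GBP diagnostic cost, opportunistically detected (not LDCT screened)
  diag_tp_noldct:
    value: 1429.23
  # GBP diagnostic cost, LDCT-screened participants without a diagnosis
  diag_tn_fn_ldct:
    value: 503.8
    psa: {dist: gamma, sd: 4.48}
  # GBP treatment cost, early-stage lung cancer
  treat_es:
    value: 4326.0
  # GBP treatment cost, late-stage lung cancer
  treat_ls:
    value: 16207.0
  # fraction of never-screen-detected late-stage cases treated after the
  # screening period (the rest die untreated)
  prop_fn_treated:
    value: 0.3885
    dsa: [0.19, 0.76]
  # fraction of early-stage cases that recur and incur late-stage treatment
  prop_es_recur:
    value: 0.5
    dsa: [0.25, 0.75]

outcomes:
  # years from start of screening to diagnosis, early-stage detections
  leadtime_es:
    value: 0.444
    psa: {dist: gamma, sd: 0.1111}
  # years from start of screening to diagnosis, late-stage cases
  leadtime_ls:
    value: 1.049
    psa: {dist: gamma, sd: 0.0561}
    dsa: [0.444, 2.0]
  # life expectancy from diagnosis (years) by stage and treatment era
  le_stage_i:
    value: 12.05
    psa: {dist: normal, sd: 0.430}
  le_stage_ii:
    value: 5.70
    psa: {dist: normal, sd: 0.271}
  le_stage_iii_prior:
    value: 2.54
    psa: {dist: normal, sd: 0.0758}
  le_stage_iv_prior:
    value: 1.38
    psa: {dist: normal, sd: 0.0571}
  le_stage_iii_immuno:
    value: 4.41
    psa: {dist: normal, sd: 0.697}
  le_stage_iv_immuno:
    value: 2.40
    psa: {dist: normal, sd: 0.4}
  # overall-survival hazard ratio, immunotherapy vs chemotherapy
  hr_immuno:
    value: 0.62
  # health utility without lung cancer
  u_nolc:
    value: 0.864
    psa: {dist: beta, a: 55543.0, b: 8734.9}
    dsa: [0.5, 1.0]
  # utility decrement for lung cancer (any stage)
  u_dec_lc:
    value: 0.112
    psa: {dist: normal, sd: 0.032}
  # additional decrement, early stage
  u_dec_es:
    value: 0.03
    psa: {dist: normal, sd: 0.0352}
  # additional decrement, late stage
  u_dec_ls:
    value: 0.07
    psa: {dist: normal, sd: 0.0291}
  # years after diagnosis during which stage decrements apply; survivors
  # revert to the no-cancer utility afterwards
  utility_decrement_years:
    value: 5.0
  # discounted lifetime QALYs of a participant who never develops lung
  # cancer (calibrated; incremental results are invariant to it)
  baseline_disc_qaly_nolc:
    value: 8.6653
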