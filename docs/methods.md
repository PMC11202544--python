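# Methods

## Model structure

The model is a single-episode cohort decision tree for a two-year screening
programme in a high-risk population. Chance nodes, in order:

1. **Disease state** at programme start: no cancer (1 − *p*), early-stage
   (*p*·*p*<sub>ES</sub>), late-stage (*p*·(1 − *p*<sub>ES</sub>)). The
   same prevalence applies to every strategy by construction, so detection
   differences are attributable to the strategy alone.
2. **Triage test**: positive with probability sens<sub>ES</sub> or
   sens<sub>LS</sub> for cancers, 1 − spec for healthy participants. A
   strategy is a (sens<sub>ES</sub>, sens<sub>LS</sub>, spec, test-cost)
   override: (0, 0, 1, 0) is no screening, (1, 1, 0, 0) universal LDCT.
3. **LDCT programme** for test-positives: detects cancer with probability
   ldct_sens (1 in the base case), clears healthy participants with
   probability ldct_spec (1 in the base case; both drop to 0.75–0.9 only
   in the DSA, which activates the FP and FN-after-LDCT pathways).
4. **Opportunistic detection** for test-negative cancers during the
   window, with stage-specific probabilities Op<sub>ES</sub>,
   Op<sub>LS</sub>. Test-positive-but-LDCT-negative cases are not offered
   opportunistic detection; they join the undetected pool.
5. **Late-treatment split**: cancer not detected during the programme is
   eventually diagnosed late; a fraction prop_fn_treated = 0.3885 is
   treated (late-stage costs, immunotherapy-era survival), the rest die
   untreated (no costs, pre-immunotherapy survival).

Undetected early-stage disease progresses to late stage before diagnosis.
Every pathway × outcome combination is carried explicitly (including the
structurally-zero FP/FN-LDCT cells of the base case) so that one code path
serves the base case, the DSA and the PSA.

## Timing conventions

- Early-stage detections are diagnosed at the early lead time (0.444 y);
  every late-stage course — screen-detected, opportunistically detected,
  or diagnosed late for treatment — uses the late lead time (1.049 y).
  That late lead time was estimated over control-arm and test-negative
  cancers, i.e. precisely over the cases that include the late-treated
  group, so the same value is the consistent diagnosis time for them; it
  also implies an average early→late progression time of ~0.6 y.
- Test costs fall at *t* = 0 (undiscounted). Diagnostic costs fall at
  diagnosis, or at 1 y (mid-programme) for participants investigated but
  never diagnosed. Treatment falls in the year of diagnosis. Recurrence
  treatment for early-stage cases is applied at the initial diagnosis time
  (no recurrence delay is modelled), slightly overstating its present
  value.
- Discounting uses a continuous-time kernel with weight 1 for the first
  year and (1.035)^−(t−1) afterwards, evaluated in closed form. An
  annual-step kernel was rejected because lead times are fractional; the
  two conventions differ by <2% on all outputs.

## Quality-adjusted lifetime

A cancer case's QALYs are assembled from three phases: the lead time at
the no-cancer utility (0.864 — asymptomatic until diagnosis), the stage
life expectancy at the stage utility (0.864 − 0.112 − 0.03 = 0.722 early;
0.864 − 0.112 − 0.07 = 0.682 late), and — for survivors beyond
`utility_decrement_years` = 5 years after diagnosis — reversion to the
no-cancer utility. The decrement window reflects the standard
cancer-survivorship convention that long-term survivors' utilities return
to the population baseline, and the decrement sources measure utilities in
the first years after treatment; in practice it affects only early-stage
survivors (mean 8.875 y from diagnosis), since all late-stage life
expectancies are under five years. Setting the parameter to infinity
recovers the lifetime-decrement variant, which is kept as a tested
limiting case; with lifetime decrements the incremental QALY gain of
triage over no screening falls from 10.7 to 9.6 per 1000.

Stage life expectancies (from diagnosis): early = mean of stage I and II
(12.05, 5.70); late detected/treated = mean of the immunotherapy-era stage
III and IV values (4.41, 2.40); never treated = mean of the
pre-immunotherapy values (2.54, 1.38). The immunotherapy values printed in
the parameter table are treated as authoritative rather than re-derived
from the hazard ratio, but the derivation machinery (Weibull fit →
five-year-survival calibration → proportional-hazards shift, HR = 0.62) is
implemented and fixture-tested.

**Baseline lifetime QALYs** for participants who never develop lung cancer
enter as one calibrated constant, `baseline_disc_qaly_nolc` = 8.6653
discounted QALYs/person, chosen so the no-screening arm total matches the
published per-1000 level. The underlying life-table inputs are not
published; every incremental result is provably invariant to this
parameter (the no-cancer mass is identical across strategies), and a test
asserts that invariance.

## Parameters and sampling

Parameters live in a YAML document (`lungscreen/data/default_parameters.yaml`)
with base value, PSA distribution and DSA range per leaf; loading
validates bounds and completeness and round-trips exactly. Gamma
distributions stated as mean ± SD are moment-matched (shape = (m/s)²,
scale = s²/m). A consistency check reports any distribution whose analytic
mean strays >1% from its base value (the packaged set has none).

PSA draws are joint-independent and shared across strategies (common
random numbers), so incremental quantities carry no between-strategy Monte
Carlo noise. Normal draws are truncated at zero only for life expectancies,
where the sub-zero mass is negligible (<10⁻³); utility-decrement normals
are sampled untruncated because ~20% of the ES-decrement mass lies below
zero and truncation would shift its mean ~40% above the base value,
decentring the PSA — a negative decrement draw simply means that draw's
stage utility sits above the less-decremented level, and the final stage
utility is clamped to [0, 1]. The whole tree being multilinear in its
parameters, the PSA mean reproduces the deterministic base case to Monte
Carlo error; a test asserts this at 3 MC SEs.

Reported 95% intervals are normal intervals on the per-draw distribution
(mean ± 1.96 SD): they describe parameter uncertainty, not Monte Carlo
error of the mean. CEAC ties (measure zero under continuous draws) split
their count equally. The CEAC grid is GBP 0–50,000 in steps of 1,000.

## Sensitivity and scenario analyses

The DSA re-evaluates all strategies one parameter at a time at the stored
min/max (prevalence 1–4%, early-stage share 25–75%, sensitivities,
specificity 0.5–1, opportunistic rates 0–1, LDCT accuracy 0.75–0.9, test
cost 59–201.5, late lead time, utilities, treated-fraction and recurrence
proportions) plus the discount rate at 0% and 6%. Scenario 1 sets the
early-stage sensitivity to 25% (late-stage sensitivity and specificity
unchanged); scenario 2 is a zero-cost random test with a 52% referral rate
regardless of disease, whose incremental point is exactly collinear with
universal LDCT through the origin (both scale the same per-screened-person
increments by the fraction screened) — a property the tests assert.

## Synthetic cohorts

`synthetic` samples every chance node per individual (Bernoulli along the
tree), draws lead times from the gamma specifications, utilities from the
beta, and survival from Weibull models (fixture shape 1.2, scale set so
the mean equals the assigned stage life expectancy) with administrative
censoring. It emulates the statistical structure the analysis assumes —
not smoking behaviour, comorbidity, recruitment or deprivation structure —
so passing recovery tests validate the estimators and the expectation
tree, not the epidemiological realism of the inputs. An
`enrich_prevalence` option oversamples cancer cases for estimator tests at
practical sizes; it is a testing device only. The microsimulation oracle
evaluates each simulated record with the same cost/QALY engines and checks
the arm means against the closed-form tree at 3 Monte Carlo SEs on one
million records; cell frequencies are checked at 3 binomial SEs.

## Problem sizes and tolerances

Default evaluation: 1000-participant cohort (all quantities are exactly
linear in cohort size), 10,000 PSA draws (vectorised; runs in well under a
second), one-million-record microsimulation for the oracle tests, 10⁵–10⁶
draws for distribution-moment checks. Statistical tests use 3-SE bounds,
Bonferroni-adjusted (3.6 SE) where several estimands are checked at once.

## Known limitations

- **Absolute per-arm cost totals** are 3–8% above the published levels
  (e.g. triage arm GBP 430k vs 414k per 1000). The published unit-cost
  appendix (per-pathway imaging composition, confirmatory work-up
  detail) is not available, and no combination of the published aggregate
  costs reproduces the printed arm totals exactly; the incremental
  comparisons — the decision-relevant quantities — agree to 0.3–1.7%.
  Tests therefore pin the increments tightly and the absolute levels
  loosely (±5%).
- Whether late-treated cases incur the full out-of-programme confirmatory
  diagnostic cost is an assumption (<1% effect on totals).
- Single screening episode: no repeat programmes, no age/sex
  stratification, no all-cause-mortality cap on cancer survival, no
  time-varying utilities beyond the five-year decrement window, no
  EVPI/EVPPI or budget-impact analysis.
- Lung-cancer lifetimes are not capped by general-population life
  expectancy; at the modelled ages and survival means the effect is
  second-order.
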