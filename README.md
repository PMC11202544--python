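# lungscreen

A decision-tree cost-effectiveness model for lung cancer screening with a
triage blood test.

## The problem

Low-dose CT (LDCT) screening finds lung cancer early, when it is still
treatable, but CT capacity is scarce and screening every high-risk person
sends the ~98% without cancer to expensive, anxiety-inducing imaging. An
autoantibody blood test offers a cheap first gate: only test-positives go on
to serial LDCT. Is that triage strategy worth it — compared with doing
nothing, and compared with giving everyone LDCT?

`lungscreen` answers this with a cohort decision tree for a high-risk
population (2% underlying cancer prevalence over a two-year window),
evaluating three strategies:

- **ecls** — blood-test triage: test everyone (sensitivity 52.2% for
  early-stage and 18.2% for late-stage disease, specificity 90.4%,
  GBP 106.50 per test); positives get 6-monthly LDCT for two years;
- **no_screening** — routine care only (a free test with sensitivity 0,
  specificity 1);
- **full_ldct** — universal 6-monthly LDCT (a free test with sensitivity 1,
  specificity 0).

## The model

Each participant traverses a probability tree over true disease state
(none / early stage / late stage, with prevalence *p* and early-stage share
*p*<sub>ES</sub>), the triage-test result, the LDCT programme for
test-positives, and opportunistic detection through routine care for
test-negative cancers (probabilities Op<sub>ES</sub>, Op<sub>LS</sub>).
Undetected early-stage disease progresses to late stage; never-screen-
detected late-stage mass splits into a treated fraction (38.85%) and a
never-treated remainder.

Each terminal cell receives:

- **lifetime QALYs** = lead time at the no-cancer utility *u*₀, then the
  stage life expectancy at the stage utility (*u*₀ minus the cancer and
  stage decrements; decrements expire 5 years after diagnosis for
  survivors). Early detections average stage I–II life expectancy from
  diagnosis; late detections the immunotherapy-era stage III–IV figures
  (obtained from pre-immunotherapy survival via a proportional-hazards
  shift, HR = 0.62); never-treated cases the pre-immunotherapy figures.
- **costs** = test (at *t* = 0) + pathway-specific diagnostic imaging +
  stage-specific treatment (half of early-stage cases later add late-stage
  treatment on recurrence), each discounted at the time it occurs.

Costs and QALYs after the first year are discounted at 3.5%/year
(continuous kernel). Strategies are compared by incremental cost, QALYs,
ICER = ΔC/ΔQ, and net monetary benefit NMB(λ) = λ·ΔQ − ΔC at
λ = GBP 20,000 and 30,000 per QALY. A 10,000-draw Monte Carlo PSA (beta
distributions for probabilities and utilities, gamma for lead times and
diagnostic costs, normal for life expectancies and utility decrements,
common draws across strategies) yields cost-effectiveness acceptability
curves; one-way DSA and two scenario analyses probe the key assumptions.

The package also ships the survival machinery behind the life-expectancy
inputs (Weibull fit to digitised Kaplan–Meier points, calibration to an
observed five-year survival, hazard-ratio adjustment) and a synthetic
individual-level trial generator used as a microsimulation oracle and for
parameter-recovery validation.

## Worked example

```python
import lungscreen as ls

params = ls.default_parameters()          # packaged base case
settings = ls.EvaluationSettings()        # 1000 people, 3.5%, 10k draws

results = {s.name: ls.evaluate_strategy(params, s, settings)
           for s in ls.default_strategies()}
inc = ls.compare(results["ecls"], results["no_screening"], (20000.0, 30000.0))
print(f"dC {inc.d_cost:,.0f}  dQ {inc.d_qaly:.1f}  ICER {inc.icer:,.0f}")
```

Running `python examples/base_case.py` prints:

```
Per 1000 participants (3.5% discounting after year one):
  ecls          cost GBP    430,428   QALYs   8570.4
  no_screening  cost GBP    250,053   QALYs   8559.7
  full_ldct     cost GBP    818,886   QALYs   8581.4

Triage test vs no screening:
  extra cost  GBP 180,375  extra QALYs 10.7  ICER GBP 16,797/QALY
  net monetary benefit at GBP 20,000/QALY: GBP 34,400
  net monetary benefit at GBP 30,000/QALY: GBP 141,787

Universal LDCT vs triage test:
  extra cost  GBP 388,458  extra QALYs 11.0  ICER GBP 35,245/QALY
```

Reading: per 1000 screened, the blood-test triage buys 10.7 QALYs for
GBP 180k — under GBP 17k per QALY, comfortably worthwhile at UK
thresholds. Upgrading everyone to LDCT buys 11 more QALYs but at GBP 35k
each, above the usual willingness to pay. The PSA
(`python examples/psa_ceac.py`) shows the triage strategy is the most
likely cost-effective choice for thresholds between ~GBP 18k and ~36k per
QALY, peaking at ~85% near GBP 25k.

Other examples: `cohort_accounting.py` (who ends up where in the tree),
`dsa_and_scenarios.py` (one-way ranges; a pessimistic-sensitivity and a
"random test" scenario), `synthetic_validation.py` (microsimulation
cross-check and parameter recovery).

## Command line

```bash
lungscreen evaluate                 # base-case tables
lungscreen psa --draws 10000 --seed 1   # PSA summary + CEAC csv/png
lungscreen dsa                      # one-way sensitivity table
lungscreen scenarios                # cost-effectiveness plane
lungscreen simulate --n 6000        # synthetic two-arm cohort
lungscreen calibrate --km km.csv --horizon 5 --target 0.4
```

All outputs are CSV (or `--format json`) plus a `manifest.json` recording
config hash, seed and version; plots are drawn from the CSVs.

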