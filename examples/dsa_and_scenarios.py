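"""One-way sensitivity analysis and the two policy scenarios.

Re-evaluates the model at the stored min/max of each ranged parameter and
for two scenarios: a pessimistic early-stage sensitivity of 25%, and a
zero-cost "random test" that refers 52% of participants regardless of
disease.
"""

import lungscreen as ls
from lungscreen.evaluate import dsa_frame

params = ls.default_parameters()
settings = ls.EvaluationSettings()

entries = ls.run_dsa(params, settings=settings,
                     parameters=["prevalence", "test_cost"])
df = dsa_frame(entries)
cols = ["parameter", "setting", "value", "strategy", "d_nmb_20000"]
print("Net-benefit (GBP, vs each comparator at 20k/QALY) under DSA:")
print(df.dropna()[cols].round({"d_nmb_20000": 0}).to_string(index=False))

plane = ls.run_scenarios(params, settings)
print("\nScenarios on the cost-effectiveness plane (vs no screening):")
print(plane[["alternative", "d_cost", "d_qaly", "icer"]].round(1)
      .to_string(index=False))

# At 1% prevalence the triage test's net benefit vs no screening turns
# negative (~ -60k GBP per 1000): screening only pays off if the target
# population is risky enough.  The random test lies on the same ray as
# universal LDCT (same ICER, 52% of the scale) — the triage test beats
# both by concentrating LDCT on likely cases.
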