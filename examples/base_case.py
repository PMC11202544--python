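"""Base-case evaluation of the three screening strategies.

Evaluates the decision tree at the packaged base-case parameters for a
cohort of 1000 high-risk participants and prints lifetime discounted
costs, QALYs and the incremental comparisons.
"""

import lungscreen as ls

params = ls.default_parameters()
settings = ls.EvaluationSettings()

results = {
    s.name: ls.evaluate_strategy(params, s, settings)
    for s in ls.default_strategies()
}

print("Per 1000 participants (3.5% discounting after year one):")
for name, res in results.items():
    print(f"  {name:13s} cost GBP {res.cost:>10,.0f}   QALYs {res.qaly:8.1f}")

inc_ns = ls.compare(results["ecls"], results["no_screening"], (20000.0, 30000.0))
inc_ld = ls.compare(results["full_ldct"], results["ecls"])
print("\nTriage test vs no screening:")
print(f"  extra cost  GBP {inc_ns.d_cost:,.0f}  extra QALYs {inc_ns.d_qaly:.1f}"
      f"  ICER GBP {inc_ns.icer:,.0f}/QALY")
for lam, nmb in inc_ns.d_nmb.items():
    print(f"  net monetary benefit at GBP {lam:,.0f}/QALY: GBP {nmb:,.0f}")
print("\nUniversal LDCT vs triage test:")
print(f"  extra cost  GBP {inc_ld.d_cost:,.0f}  extra QALYs {inc_ld.d_qaly:.1f}"
      f"  ICER GBP {inc_ld.icer:,.0f}/QALY")

# A positive NMB means the strategy buys QALYs below the stated
# willingness-to-pay; the triage test is worthwhile at 20k and 30k/QALY,
# while stepping up to universal LDCT costs ~35k per additional QALY.
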