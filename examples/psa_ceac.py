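"""Probabilistic sensitivity analysis and acceptability curves.

Draws 10,000 joint parameter realisations from the base-case
distributions, evaluates all three strategies on common draws, and
reports which strategy is most likely to be cost-effective across
willingness-to-pay thresholds.
"""

import lungscreen as ls

params = ls.default_parameters()
psa = ls.run_psa(params, settings=ls.EvaluationSettings(), seed=1)

print(psa.summary[["strategy", "cost_mean", "qaly_mean"]].round(1)
      .to_string(index=False))

table = psa.ceac.pivot(index="threshold", columns="strategy",
                       values="probability")
print("\nProbability cost-effective at selected thresholds:")
print(table.loc[[10000, 18000, 20000, 25000, 30000, 35000, 40000]]
      .round(3).to_string())

ecls = table["ecls"]
print(f"\nTriage-test peak: {100 * ecls.max():.1f}% at "
      f"GBP {ecls.idxmax():,.0f}/QALY")

# Below ~18k/QALY no screening is most often best; between ~18k and ~36k
# the triage test leads (peaking near 25k); above that universal LDCT
# takes over — the published decision pattern.
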