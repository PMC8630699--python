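"""Probabilistic sensitivity analysis and acceptability curve.

Propagates parameter uncertainty (gamma costs, lognormal hazard ratios,
beta utilities and probabilities, moment-matched to the published ranges)
through 10,000 Monte Carlo model runs and reports how often the
combination strategy has the higher net monetary benefit.
"""

from melcea import run_psa
from melcea.plots import ceac_plot

psa = run_psa(n_draws=10_000, seed=1)

for wtp in (50_000, 100_000, 150_000):
    p = psa.probability_cost_effective(float(wtp))
    print(f"P(cost-effective) at ${wtp:>7,}/QALY: {100 * p:5.1f}%")
print()
print(
    "At the conventional US threshold of $150,000/QALY the combination is\n"
    "cost-effective in the large majority of simulations; at $50,000/QALY\n"
    "it rarely is."
)

ax = ceac_plot(psa.ceac)
ax.figure.savefig("ceac.png", bbox_inches="tight", dpi=120)
print("Saved ceac.png")
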