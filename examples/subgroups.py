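"""Subgroup analysis over the pre-specified hazard-ratio table.

Each subgroup replaces the progression-free and overall-survival hazard
ratios (point estimates and confidence intervals) while keeping every other
input at baseline; the deterministic ICER and the probabilistic chance of
cost-effectiveness at $150,000/QALY are reported per row.
"""

from melcea import run_subgroups

table = run_subgroups(n_draws=2_000, seed=1)
table["ce_probability"] = (100 * table["ce_probability"]).round(0)
print(
    table.to_string(
        index=False,
        formatters={"icer_per_qaly": "{:,.0f}".format, "ce_probability": "{:.0f}%".format},
    )
)
print()
lo = table.loc[table["icer_per_qaly"].idxmin()]
hi = table.loc[table["icer_per_qaly"].idxmax()]
print(
    f"Most favourable: {lo.subgroup} (${lo.icer_per_qaly:,.0f}/QALY);\n"
    f"least favourable: {hi.subgroup} (${hi.icer_per_qaly:,.0f}/QALY) — the\n"
    "only setting clearly above the willingness-to-pay threshold."
)
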