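# Methods

## Model structure

A cohort state-transition model follows a hypothetical cohort of patients
with metastatic melanoma resistant to anti-PD-(L)1 monotherapy from the
start of second-line therapy to death. Four mutually exclusive states:
progression-free with treatment response, progression-free with stable
disease, progressed disease (best supportive care until death), and dead.
Everyone starts progression-free; progression and death are absorbing in
the usual one-directional sense.

Occupancy is computed in **partitioned-survival** form: progression-free
membership equals the progression-free survival function, death equals one
minus overall survival, and the progressed state is the difference,
clamped at zero (with a logged warning) wherever a hazard-ratio combination
makes the adjusted PFS curve cross above OS — which genuinely happens for
subgroups with a weak OS effect but a strong PFS effect. The split of
progression-free time into response versus stable disease uses a constant
arm-specific response share (0.31 combination, 0.13 ipilimumab); no
time course of response is modelled because only a single response
percentage per arm is available. A transition-probability mode (a
three-state chain driven by per-cycle conditional exit and death
probabilities derived from the same curves) is available behind
`ModelConfig.occupancy_mode` for comparison; it reproduces the same
marginals up to grid placement and agrees with the partitioned mode to
about 1% on discounted life-years.

## Survival inputs and extrapolation

The ipilimumab arm's OS and PFS are log-logistic,
`S(t) = 1/(1 + θ t^κ)`, `t` in months — OS (θ = 0.03916796, κ = 1.52458,
median 8.37 months), PFS (θ = 0.1380415, κ = 1.922389, median 2.80
months). The published model reports only "Theta" and "Kappa" without a
functional form or time unit; this parameterization and months were
adopted because they reproduce the published per-arm life-years and the
PFS median, and both are explicit in `SurvivalSpec`.

The combination arm is derived by **proportional hazards** on the fitted
baseline, `S₁ = S₀^HR` (OS HR 0.50, PFS HR 0.69). Whether the original
analysis used a PH adjustment or an AFT factor is not stated; PH was
chosen because it reproduces the published combination-arm life-years
(an AFT or proportional-odds reading gives 2.3–2.0 discounted LYs against
the published 3.80). An AFT mode remains available via
`apply_hazard_ratio(..., mode="aft")`.

Six families are supported for the fitting stage (exponential, Weibull,
lognormal, log-logistic, Gompertz, generalized gamma). The generalized
gamma uses the log-time (μ, σ, Q) parameterization, nesting the lognormal
at Q = 0 and the Weibull at Q = 1. Gompertz fits with negative shape are
admitted but flagged improper (`SurvivalSpec.is_proper`), since their
survival plateaus and an extrapolated mean need not exist.

## Cycle grid, discounting, horizon

- **Cycle length**: 21 days, i.e. 21/30.4375 ≈ 0.690 months (exactly
  3 weeks of disease-management billing per cycle).
- **Horizon**: 480 months (40 years), at which point residual survival is
  about 0.2% in the ipilimumab arm and 4.6% in the combination arm's
  heavy log-logistic tail. A shorter operationalization of "lifetime"
  (e.g. 10 years) truncates the combination arm's tail enough to lose a
  quarter of its published life-years; 40 years reconciles both arms with
  the published per-arm results. Configurable.
- **Discounting**: 3% per annum, applied continuously per cycle as
  `1.03^(−t/12)` at the cycle's evaluation time; life-years, QALYs and all
  costs are discounted alike.
- **Half-cycle correction**: on by default — state membership is evaluated
  at cycle midpoints (midpoint-rule integration of the survival area).
  Halving the cycle length moves discounted life-years by well under 0.5%.

## Costing

All prices are 2021 USD. Drug acquisition uses per-mg prices (106% of
average sales price) at a fixed 70 kg body weight, under the FDA
schedules: ipilimumab 3 mg/kg q3w ×4 (ipilimumab arm); ipilimumab
3 mg/kg + nivolumab 1 mg/kg q3w ×4 then nivolumab 240 mg q2w (99% of the
combination arm); ipilimumab 1 mg/kg + pembrolizumab 2 mg/kg q3w ×4 then
pembrolizumab 200 mg q3w (1%). Induction doses are charged at cycle-start
times weighted by the probability of still being progression-free at each
scheduled administration; maintenance anti-PD-1 continues until
progression with no duration cap (a cap is configurable), with nivolumab's
q2w schedule accruing 1.5 expected administrations per 3-week cycle.
Administration fees bill the first infusion hour once per visit and each
started additional hour; combined same-day infusions bill the first hour
once. Infusion durations (ipilimumab 1.5 h, anti-PD-1 0.5 h) follow the
product labels and are configurable. No drug wastage is modelled
(per-mg billing).

Progression-free disease-management costs split by treatment status: $189
per week while any drug is still being administered, $590 per week
afterwards (relevant only to the ipilimumab arm, whose treatment ends
after induction). Terminal care ($18,042) is a one-time cost attached to
each cycle's incident deaths.

**Best supportive care ($4,492)** is charged as a **one-time cost at exit
from the progression-free state**. The published table states no unit for
this item. Charging it per 3-week cycle of progressed-disease occupancy is
arithmetically incompatible with the published totals: the combination arm
spends ~55 discounted cycles progressed, which alone would add ~$211k to
an arm whose published total cost is $243,480, and would push the ICER
near $165k/QALY against the published $73,163. The one-time reading lands
both arm totals within 4% of the published values. A `per_cycle` mode is
exposed for scenario analysis. The one-off is charged against the
per-cycle decline of the PFS curve (everyone leaving the progression-free
state, including the small fraction who die without recorded progression);
the distinction is worth under $500 per arm.

Adverse-event management, testing and hospitalization costs are excluded
(equal across arms or explicitly out of scope).

## Sensitivity analyses

**One-way**: each parameter in turn is set to the ends of its published
range (95% CI or ±20%) with all others at baseline; parameters are ranked
by the width of the induced ICER interval.

**Probabilistic** (default 10,000 draws): costs are gamma, hazard ratios
lognormal, utilities and probabilities beta. Gamma and beta are
moment-matched to (baseline, sd) with sd = (max − min)/3.92 — the normal
95%-interval width — and the lognormal uses meanlog = ln(baseline),
sdlog = (ln max − ln min)/3.92. The survival-curve parameters (θ, κ) stay
fixed: no distribution is published for them. Beta moment matches that
fall outside the feasible domain are clamped with a logged warning (none
of the bundled parameters trigger this). The acceptability curve is the
fraction of draws in which the combination has the higher net monetary
benefit (NMB = WTP × QALY − cost), evaluated on a $0–200,000 grid in
$5,000 steps. Sampling is vectorized: the whole cohort model broadcasts a
leading draws axis, so a 10,000-draw PSA is a single model evaluation and
is bit-reproducible for a given seed.

**Subgroups**: each row of the bundled table replaces both hazard ratios
(point estimates and CIs) while keeping every other input — including its
PSA distributions — at base; per row the deterministic ICER and the
probabilistic chance of cost-effectiveness at $150,000/QALY (2,000 draws
per row, independently seeded per row) are reported. Whether the original
subgroup probabilities also resampled costs and utilities is unstated;
they are resampled here.

The base-case ICER is always computed from unrounded increments; the
published rounded increments ($101,397 / 1.39) do not reproduce the
published ICER, confirming that convention.

## Curve reconstruction stage

`reconstruct_ipd` inverts a digitized KM curve with numbers-at-risk into
pseudo individual-patient data: per risk-table interval, a censoring count
is guessed, spread uniformly over the interval, and iteratively adjusted
until the implied number at risk matches the next printed count; event
counts per coordinate follow from successive survival ratios against the
running product-limit estimate. Patients still at risk after the last
coordinate are censored there. Events attributed to a coordinate are dated
at the coordinate itself by default (exact when the curve was digitized at
its visible steps); `event_placement="midpoint"` dates them mid-way into
the preceding gap, which removes the systematic right-shift that arises
when the curve is read off a uniform grid that is coarse relative to the
median — with a 40-point grid and a 2.8-month median, coordinate placement
biases the fitted (θ, κ) by roughly (−40%, +13%), midpoint placement to
within (18%, 4%).

Parametric fitting maximizes the right-censored log-likelihood
`Σ_events ln f(t) + Σ_censored ln S(t)` by multi-start Nelder-Mead with a
BFGS polish on an unconstrained transform of each family's parameters;
non-convergence is reported on the result object. Model selection is
minimal AIC (= 2k − 2 lnL), ties broken by fewer parameters then family
order; the published "visual inspection" criterion has no computational
counterpart.

## Synthetic data

`simulate_ipd` draws event times by inverse CDF from any supported family,
with uniform accrual over a configurable window and administrative
censoring at a fixed cutoff — emulating the staggered follow-up of the
retrospective cohort behind the published curves (which were never
released as data; every fixture here is synthetic with known truth). A
mandatory seed drives a local generator; no global RNG state is touched.
What passing the round-trip tests shows is that the reconstruction and
fitting machinery is faithful for curves of this shape, sample size
(~160–500 per arm) and censoring pattern; it cannot show that the
published curves themselves were digitized accurately, and the generator
does not emulate digitization noise in the survival coordinates (clicks
are read exactly), informative censoring, or reporting granularity in the
published risk tables.

## Problem sizes and numerical choices

Default runs use 696 cycles (40 years of 3-week cycles); the PSA uses
10,000 draws and subgroup PSAs 2,000 draws per row, matching the scale of
the published analysis while keeping a full acceptance run under ten
seconds. Fitting tolerances: 1e-8 simplex parameter tolerance with a
1e-10 likelihood tolerance, event times floored at 1e-6 months to keep
log-densities finite. ICERs with a zero effect increment are reported as
undefined (NaN), never as ±infinity; dominance (cheaper and more
effective) is flagged separately.

## Known limitations

- The horizon, half-cycle handling, BSC cost unit and HR application are
  unreported conventions of the source analysis; the defaults here are the
  combination that reproduces its published tables, each exposed in
  configuration. Component-level cost breakdowns are therefore less
  certain than the totals.
- Utilities are time-constant and response shares time-invariant; no
  tunnel states, time-varying hazard ratios, cure fractions or
  individual-level heterogeneity.
- The reconstruction stage is validated only on synthetic curves; the
  original figures are not available at digitization quality.
- Subgroup analyses inherit the base arm's cost structure; only the
  hazard ratios vary.
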