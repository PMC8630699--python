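"""Incremental cost-effectiveness analyses.

Base-case comparison of ipilimumab plus anti-PD-1 against ipilimumab alone,
one-way (tornado) sensitivity analysis over every Table-style parameter
range, probabilistic sensitivity analysis with the cost-effectiveness
acceptability curve, and the pre-specified subgroup analysis in which both
hazard ratios are replaced row by row.

All analyses run through a single vectorized arm evaluation: hazard ratios,
utilities, response shares and prices may be scalars (deterministic runs)
or draw vectors (PSA), broadcast through the cohort trace and cost model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    ModelConfig,
    UtilitySet,
    accrue_life_years,
    accrue_qalys,
    build_trace,
)
from .costs import PriceTable, combination_arm, ipilimumab_arm, accrue_total_cost
from .parameters import ParameterSet, load_parameters, load_subgroups
from .survival import apply_hazard_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "ArmResult",
    "CeaResult",
    "PsaResult",
    "run_base_case",
    "net_monetary_benefit",
    "one_way_sa",
    "sample_parameters",
    "run_psa",
    "run_subgroups",
    "DEFAULT_WTP_GRID",
]

#: CEAC willingness-to-pay grid: $0 to $200,000/QALY in $5,000 steps.
DEFAULT_WTP_GRID = np.arange(0, 200001, 5000, dtype=float)


@dataclass
class ArmResult:
    """Discounted outcomes of one strategy."""

    name: str
    life_years: np.ndarray
    qalys: np.ndarray
    cost: np.ndarray
    cost_breakdown: dict


@dataclass
class CeaResult:
    """Pairwise incremental results (combination minus ipilimumab).

    ``icer_per_qaly`` / ``icer_per_ly`` are computed from the unrounded
    increments and are NaN where the effect increment is zero (reported as
    undefined rather than +/-inf).  ``dominance`` is "combination" when it
    is cheaper and more effective, "ipilimumab" for the reverse, else "".
    """

    ipilimumab: ArmResult
    combination: ArmResult

    @property
    def d_cost(self):
        return self.combination.cost - self.ipilimumab.cost

    @property
    def d_qalys(self):
        return self.combination.qalys - self.ipilimumab.qalys

    @property
    def d_life_years(self):
        return self.combination.life_years - self.ipilimumab.life_years

    @property
    def icer_per_qaly(self):
        return _safe_ratio(self.d_cost, self.d_qalys)

    @property
    def icer_per_ly(self):
        return _safe_ratio(self.d_cost, self.d_life_years)

    @property
    def dominance(self) -> str:
        dc, dq = float(np.squeeze(self.d_cost)), float(np.squeeze(self.d_qalys))
        if dc < 0 and dq > 0:
            return "combination"
        if dc > 0 and dq < 0:
            return "ipilimumab"
        return ""

    def summary(self) -> pd.DataFrame:
        rows = []
        for arm in (self.ipilimumab, self.combination):
            rows.append(
                {
                    "strategy": arm.name,
                    "life_years": float(np.squeeze(arm.life_years)),
                    "qalys": float(np.squeeze(arm.qalys)),
                    "cost": float(np.squeeze(arm.cost)),
                }
            )
        rows.append(
            {
                "strategy": "incremental",
                "life_years": float(np.squeeze(self.d_life_years)),
                "qalys": float(np.squeeze(self.d_qalys)),
                "cost": float(np.squeeze(self.d_cost)),
            }
        )
        return pd.DataFrame(rows)


def _safe_ratio(num, den):
    num, den = np.asarray(num, dtype=float), np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


def net_monetary_benefit(cost, qaly, wtp):
    """NMB = WTP x QALYs - cost; the strategy with the higher NMB at a
    given willingness-to-pay is preferred."""
    if np.any(np.asarray(wtp) < 0):
        raise ValueError("willingness-to-pay must be >= 0")
    return np.asarray(wtp, dtype=float) * np.asarray(qaly, dtype=float) - np.asarray(
        cost, dtype=float
    )


def _prices_from(values: dict) -> PriceTable:
    return PriceTable(
        ipilimumab_per_mg=values["cost_ipilimumab_per_mg"],
        nivolumab_per_mg=values["cost_nivolumab_per_mg"],
        pembrolizumab_per_mg=values["cost_pembrolizumab_per_mg"],
        bsc=values["cost_bsc"],
        mgmt_pfd_on_tx_per_week=values["cost_mgmt_on_per_week"],
        mgmt_pfd_off_tx_per_week=values["cost_mgmt_off_per_week"],
        terminal_care=values["cost_terminal_care"],
        admin_first_hour=values["cost_admin_first_hour"],
        admin_additional_hour=values["cost_admin_additional_hour"],
    )


def _evaluate_arms(pset: ParameterSet, values: dict, cfg: ModelConfig):
    """Run both strategies under one (possibly vectorized) value set."""
    prices = _prices_from(values)
    weight = float(pset.settings.get("patient_weight_kg", 70))
    nivo_share = float(pset.settings.get("nivolumab_share", 0.99))

    arms = {}
    for name in ("ipilimumab", "combination"):
        if name == "combination":
            os_fn = apply_hazard_ratio(pset.os_spec, values["hr_os"], cfg.hr_mode)
            pfs_fn = apply_hazard_ratio(pset.pfs_spec, values["hr_pfs"], cfg.hr_mode)
            share = values["response_share_combination"]
            arm_cfg = combination_arm(weight, nivo_share)
        else:
            os_fn = pset.os_spec.survival
            pfs_fn = pset.pfs_spec.survival
            share = values["response_share_ipilimumab"]
            arm_cfg = ipilimumab_arm(weight)

        trace = build_trace(os_fn, pfs_fn, cfg, share)
        utilities = UtilitySet(
            response_share=share,
            u_response=values["u_response"],
            u_stable=values["u_stable"],
            u_progressed=values["u_progressed"],
        )
        breakdown = accrue_total_cost(trace, arm_cfg, prices, cfg)
        arms[name] = ArmResult(
            name=name,
            life_years=accrue_life_years(trace, cfg),
            qalys=accrue_qalys(trace, utilities, cfg),
            cost=breakdown.total,
            cost_breakdown=breakdown.as_dict(),
        )
    return CeaResult(ipilimumab=arms["ipilimumab"], combination=arms["combination"])


def run_base_case(
    pset: ParameterSet | None = None, cfg: ModelConfig | None = None
) -> CeaResult:
    """Deterministic run with every parameter at its baseline."""
    pset = pset or load_parameters()
    cfg = cfg or ModelConfig()
    return _evaluate_arms(pset, pset.baseline_values(), cfg)


def one_way_sa(
    pset: ParameterSet | None = None, cfg: ModelConfig | None = None
) -> pd.DataFrame:
    """Tornado table: each parameter pushed to its range ends one at a time,
    all others at baseline; sorted by ICER span, widest first."""
    pset = pset or load_parameters()
    cfg = cfg or ModelConfig()
    base = pset.baseline_values()
    rows = []
    for p in pset:
        icers = {}
        for end, value in (("low", p.low), ("high", p.high)):
            values = dict(base)
            values[p.name] = value
            icers[end] = float(_evaluate_arms(pset, values, cfg).icer_per_qaly)
        rows.append(
            {
                "parameter": p.name,
                "label": p.label or p.name,
                "low": p.low,
                "high": p.high,
                "icer_at_low": icers["low"],
                "icer_at_high": icers["high"],
                "span": abs(icers["high"] - icers["low"]),
            }
        )
    table = pd.DataFrame(rows).sort_values("span", ascending=False, kind="mergesort")
    return table.reset_index(drop=True)


#: Normal 95% interval width in standard deviations, used to convert a
#: (min, max) range into a standard deviation (or a log-sd for HRs).
_CI_WIDTH_SD = 3.92


def sample_parameters(
    pset: ParameterSet, rng: np.random.Generator, n_draws: int
) -> dict:
    """Draw a PSA parameter matrix: gamma for costs and beta for
    utilities/probabilities moment-matched to (baseline, sd) with
    sd = (max - min)/3.92; lognormal for HRs with meanlog = ln(baseline)
    and sdlog = (ln max - ln min)/3.92.  Fixed/degenerate parameters stay
    constant.  Samples outside [min is not enforced]; infeasible beta
    moment matches are clamped with a warning."""
    draws = {}
    for p in pset:
        if p.is_fixed:
            draws[p.name] = np.full(n_draws, p.baseline)
            continue
        if p.distribution == "gamma":
            sd = (p.high - p.low) / _CI_WIDTH_SD
            shape = (p.baseline / sd) ** 2
            scale = sd**2 / p.baseline
            draws[p.name] = rng.gamma(shape, scale, size=n_draws)
        elif p.distribution == "lognormal":
            sdlog = (np.log(p.high) - np.log(p.low)) / _CI_WIDTH_SD
            draws[p.name] = rng.lognormal(np.log(p.baseline), sdlog, size=n_draws)
        elif p.distribution == "beta":
            m = p.baseline
            sd = (p.high - p.low) / _CI_WIDTH_SD
            nu = m * (1 - m) / sd**2 - 1.0
            if nu <= 0:
                logger.warning(
                    "beta moment match infeasible for %s (mean %.3g, sd %.3g); "
                    "clamping concentration to 1",
                    p.name,
                    m,
                    sd,
                )
                nu = 1.0
            draws[p.name] = rng.beta(m * nu, (1 - m) * nu, size=n_draws)
        else:  # pragma: no cover
            raise AssertionError(p.distribution)
    return draws


@dataclass
class PsaResult:
    """Probabilistic sensitivity analysis output: per-draw arm outcomes and
    the cost-effectiveness acceptability curve on a WTP grid."""

    draws: dict
    result: CeaResult
    wtp_grid: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.result.d_cost)

    def probability_cost_effective(self, wtp) -> np.ndarray:
        """Fraction of draws in which the combination has the higher net
        monetary benefit at the given willingness-to-pay value(s)."""
        wtp = np.atleast_1d(np.asarray(wtp, dtype=float))
        dq, dc = self.result.d_qalys, self.result.d_cost
        wins = wtp[:, None] * dq[None, :] - dc[None, :] > 0
        out = wins.mean(axis=1)
        return out if out.shape != (1,) else float(out[0])

    @property
    def ceac(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": self.wtp_grid,
                "probability_cost_effective": np.atleast_1d(
                    self.probability_cost_effective(self.wtp_grid)
                ),
            }
        )


def run_psa(
    pset: ParameterSet | None = None,
    cfg: ModelConfig | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> PsaResult:
    """Monte Carlo propagation of parameter uncertainty (default 10,000
    draws); reproducible for a given seed."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    pset = pset or load_parameters()
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(seed)
    draws = sample_parameters(pset, rng, n_draws)
    result = _evaluate_arms(pset, draws, cfg)
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    return PsaResult(draws=draws, result=result, wtp_grid=grid, seed=seed)


def run_subgroups(
    pset: ParameterSet | None = None,
    subgroups: pd.DataFrame | None = None,
    cfg: ModelConfig | None = None,
    n_draws: int = 2_000,
    seed: int = 0,
    wtp: float = 150_000.0,
) -> pd.DataFrame:
    """Subgroup analysis: per row, replace the OS and PFS hazard ratios
    (baseline and CI) with the subgroup's values, keep everything else at
    base, and report the deterministic ICER plus the PSA probability of
    cost-effectiveness at the given WTP."""
    pset = pset or load_parameters()
    subgroups = subgroups if subgroups is not None else load_subgroups()
    cfg = cfg or ModelConfig()

    rows = []
    for i, row in enumerate(subgroups.itertuples(index=False)):
        sub_pset = pset.replace_parameter(
            "hr_pfs", baseline=row.pfs_hr, low=row.pfs_ci_low, high=row.pfs_ci_high
        ).replace_parameter(
            "hr_os", baseline=row.os_hr, low=row.os_ci_low, high=row.os_ci_high
        )
        det = _evaluate_arms(sub_pset, sub_pset.baseline_values(), cfg)
        psa = run_psa(
            sub_pset, cfg, n_draws=n_draws, seed=np.random.SeedSequence([seed, i])
        )
        rows.append(
            {
                "subgroup": row.subgroup,
                "pfs_hr": row.pfs_hr,
                "os_hr": row.os_hr,
                "icer_per_qaly": float(det.icer_per_qaly),
                "ce_probability": float(psa.probability_cost_effective(wtp)),
            }
        )
    return pd.DataFrame(rows)
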