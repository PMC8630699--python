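"""Costing of the treatment strategies (2021 USD, US payer perspective).

Covers drug acquisition under the FDA dosing schedules at a 70 kg body
weight, infusion administration fees, progression-free disease management
(on- vs off-treatment weekly rates), best supportive care at progression,
and one-time terminal care at death.  Adverse-event management, testing and
hospitalization costs are out of scope (equal across arms or excluded).

Doses only accrue while patients remain progression-free: each scheduled
administration is weighted by the probability of still being
progression-free at its scheduled time, and maintenance anti-PD-1 continues
until progression.  All price fields accept arrays (probabilistic draws)
broadcast against the cohort trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortTrace, ModelConfig

__all__ = [
    "PriceTable",
    "DrugDose",
    "Regimen",
    "ArmCostConfig",
    "CostBreakdown",
    "dose_cost",
    "administration_cost",
    "expected_drug_cost_per_cycle",
    "accrue_total_cost",
    "ipilimumab_regimen",
    "ipilimumab_nivolumab_regimen",
    "ipilimumab_pembrolizumab_regimen",
    "ipilimumab_arm",
    "combination_arm",
]

#: A 3-week cycle is exactly 3 weeks of disease-management billing.
WEEKS_PER_CYCLE = 3.0


@dataclass(frozen=True)
class PriceTable:
    """Unit prices (2021 USD).  Drug prices are per mg at 106% of the
    average sales price; administration fees follow the CMS physician fee
    schedule (first infusion hour, then each started additional hour)."""

    ipilimumab_per_mg: float = 166.0
    nivolumab_per_mg: float = 30.0
    pembrolizumab_per_mg: float = 55.0
    bsc: float = 4492.0
    mgmt_pfd_on_tx_per_week: float = 189.0
    mgmt_pfd_off_tx_per_week: float = 590.0
    terminal_care: float = 18042.0
    admin_first_hour: float = 148.0
    admin_additional_hour: float = 31.0

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if np.any(np.asarray(value) < 0):
                raise ValueError(f"price {name} must be non-negative")

    def per_mg(self, drug: str):
        try:
            return getattr(self, f"{drug}_per_mg")
        except AttributeError:
            raise KeyError(f"no per-mg price for drug {drug!r}") from None

    def with_(self, **kwargs) -> "PriceTable":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DrugDose:
    """One drug component of a regimen: either a weight-based dose
    (mg_per_kg) or a flat dose (flat_mg), with its infusion duration."""

    drug: str
    mg_per_kg: float | None = None
    flat_mg: float | None = None
    infusion_hours: float = 0.5

    def __post_init__(self):
        if (self.mg_per_kg is None) == (self.flat_mg is None):
            raise ValueError("specify exactly one of mg_per_kg or flat_mg")
        dose = self.mg_per_kg if self.mg_per_kg is not None else self.flat_mg
        if dose < 0:
            raise ValueError("dose must be non-negative")


@dataclass(frozen=True)
class Regimen:
    """A dosing schedule: an induction block given once per 3-week cycle
    for ``n_induction_doses`` doses (all components infused the same day),
    optionally followed by a maintenance component administered
    ``maintenance_admins_per_cycle`` times per cycle until progression
    (or ``maintenance_max_cycles``, if capped)."""

    name: str
    induction: tuple
    n_induction_doses: int = 4
    maintenance: DrugDose | None = None
    maintenance_admins_per_cycle: float = 1.0
    maintenance_max_cycles: int | None = None
    patient_weight_kg: float = 70.0

    def __post_init__(self):
        if self.n_induction_doses < 0:
            raise ValueError("number of induction doses must be >= 0")
        object.__setattr__(self, "induction", tuple(self.induction))


@dataclass(frozen=True)
class ArmCostConfig:
    """Regimen mix of one arm (weights sum to 1) plus the best-supportive-
    care accrual convention: ``bsc_mode='one_time'`` charges the BSC cost
    once on exit from the progression-free state; ``'per_cycle'`` charges it
    every cycle of progressed-disease occupancy."""

    regimens: tuple
    bsc_mode: str = "one_time"

    def __post_init__(self):
        object.__setattr__(self, "regimens", tuple(self.regimens))
        weights = [w for _, w in self.regimens]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("regimen mix weights must sum to 1")
        if self.bsc_mode not in ("one_time", "per_cycle"):
            raise ValueError(f"unknown bsc mode {self.bsc_mode!r}")


def ipilimumab_regimen(weight_kg: float = 70.0) -> Regimen:
    """Ipilimumab 3 mg/kg every 3 weeks for 4 doses."""
    return Regimen(
        name="ipilimumab",
        induction=(DrugDose("ipilimumab", mg_per_kg=3.0, infusion_hours=1.5),),
        patient_weight_kg=weight_kg,
    )


def ipilimumab_nivolumab_regimen(weight_kg: float = 70.0) -> Regimen:
    """Ipilimumab 3 mg/kg + nivolumab 1 mg/kg q3w x 4, then nivolumab
    240 mg every 2 weeks (1.5 expected administrations per 3-week cycle)."""
    return Regimen(
        name="ipilimumab+nivolumab",
        induction=(
            DrugDose("ipilimumab", mg_per_kg=3.0, infusion_hours=1.5),
            DrugDose("nivolumab", mg_per_kg=1.0, infusion_hours=0.5),
        ),
        maintenance=DrugDose("nivolumab", flat_mg=240.0, infusion_hours=0.5),
        maintenance_admins_per_cycle=1.5,
        patient_weight_kg=weight_kg,
    )


def ipilimumab_pembrolizumab_regimen(weight_kg: float = 70.0) -> Regimen:
    """Ipilimumab 1 mg/kg + pembrolizumab 2 mg/kg q3w x 4, then
    pembrolizumab 200 mg every 3 weeks."""
    return Regimen(
        name="ipilimumab+pembrolizumab",
        induction=(
            DrugDose("ipilimumab", mg_per_kg=1.0, infusion_hours=1.5),
            DrugDose("pembrolizumab", mg_per_kg=2.0, infusion_hours=0.5),
        ),
        maintenance=DrugDose("pembrolizumab", flat_mg=200.0, infusion_hours=0.5),
        maintenance_admins_per_cycle=1.0,
        patient_weight_kg=weight_kg,
    )


def ipilimumab_arm(weight_kg: float = 70.0, bsc_mode: str = "one_time") -> ArmCostConfig:
    return ArmCostConfig(((ipilimumab_regimen(weight_kg), 1.0),), bsc_mode=bsc_mode)


def combination_arm(
    weight_kg: float = 70.0,
    nivolumab_share: float = 0.99,
    bsc_mode: str = "one_time",
) -> ArmCostConfig:
    """99% ipilimumab+nivolumab / 1% ipilimumab+pembrolizumab mix."""
    return ArmCostConfig(
        (
            (ipilimumab_nivolumab_regimen(weight_kg), nivolumab_share),
            (ipilimumab_pembrolizumab_regimen(weight_kg), 1.0 - nivolumab_share),
        ),
        bsc_mode=bsc_mode,
    )


def dose_cost(dose: DrugDose, prices: PriceTable, weight_kg: float):
    """Acquisition cost of one administration of one drug component."""
    price = prices.per_mg(dose.drug)
    if dose.mg_per_kg is not None:
        return price * dose.mg_per_kg * weight_kg
    return price * dose.flat_mg


def administration_cost(infusion_hours: float, prices: PriceTable):
    """Infusion fee for one visit: first hour, plus each *started*
    additional hour (partial hours round up)."""
    if infusion_hours <= 0:
        raise ValueError("infusion duration must be positive")
    additional = max(0, math.ceil(infusion_hours - 1.0 - 1e-9))
    return prices.admin_first_hour + additional * prices.admin_additional_hour


def _col(x):
    """Append a cycle axis to a draws-shaped array so it broadcasts against
    (draws, cycles) occupancy arrays."""
    x = np.asarray(x, dtype=float)
    return x[..., None] if x.ndim else x


@dataclass
class CostBreakdown:
    """Discounted cost components of one arm; ``total`` is their exact sum."""

    drug: np.ndarray
    administration: np.ndarray
    management_on_treatment: np.ndarray
    management_off_treatment: np.ndarray
    bsc: np.ndarray
    terminal_care: np.ndarray

    @property
    def total(self):
        return (
            self.drug
            + self.administration
            + self.management_on_treatment
            + self.management_off_treatment
            + self.bsc
            + self.terminal_care
        )

    def as_dict(self) -> dict:
        d = {
            "drug": self.drug,
            "administration": self.administration,
            "management_on_treatment": self.management_on_treatment,
            "management_off_treatment": self.management_off_treatment,
            "bsc": self.bsc,
            "terminal_care": self.terminal_care,
        }
        d["total"] = self.total
        return d


def _regimen_cycle_costs(trace, regimen, prices, cfg):
    """Per-cycle expected drug and administration cost vectors for one
    regimen, undiscounted, plus the number of cycles with scheduled drug."""
    n = trace.n_cycles
    pf_bound = trace.pf_boundary
    pf_eval = trace.progression_free

    per_visit_drug = per_visit_admin = 0.0
    n_ind = min(regimen.n_induction_doses, n) if regimen.induction else 0
    if n_ind:
        per_visit_drug = sum(
            dose_cost(d, prices, regimen.patient_weight_kg) for d in regimen.induction
        )
        visit_hours = sum(d.infusion_hours for d in regimen.induction)
        per_visit_admin = administration_cost(visit_hours, prices)

    lead = np.broadcast_shapes(
        pf_eval.shape[:-1],
        np.shape(per_visit_drug),
        np.shape(per_visit_admin),
        np.shape(prices.admin_first_hour),
    )
    drug = np.zeros(lead + (n,))
    admin = np.zeros(lead + (n,))
    if n_ind:
        k = np.arange(n_ind)
        drug[..., :n_ind] += _col(per_visit_drug) * pf_bound[..., k]
        admin[..., :n_ind] += _col(per_visit_admin) * pf_bound[..., k]

    if regimen.maintenance is not None:
        start = regimen.n_induction_doses
        stop = n
        if regimen.maintenance_max_cycles is not None:
            stop = min(n, start + regimen.maintenance_max_cycles)
        if stop > start:
            per_admin_drug = dose_cost(
                regimen.maintenance, prices, regimen.patient_weight_kg
            )
            per_admin_fee = administration_cost(
                regimen.maintenance.infusion_hours, prices
            )
            admins = regimen.maintenance_admins_per_cycle * pf_eval[..., start:stop]
            drug[..., start:stop] += _col(per_admin_drug) * admins
            admin[..., start:stop] += _col(per_admin_fee) * admins
    return drug, admin


def expected_drug_cost_per_cycle(
    trace: CohortTrace,
    arm_cfg: ArmCostConfig,
    prices: PriceTable,
    cfg: ModelConfig | None = None,
) -> dict:
    """Undiscounted per-cycle expected drug and administration cost vectors,
    mixed over the arm's regimens.  Induction doses are weighted by the
    probability of being progression-free at each scheduled administration
    (cycle starts); maintenance accrues with progression-free occupancy."""
    cfg = cfg or trace.cfg
    drug = 0.0
    admin = 0.0
    for regimen, w in arm_cfg.regimens:
        d, a = _regimen_cycle_costs(trace, regimen, prices, cfg)
        drug = drug + w * d
        admin = admin + w * a
    return {"drug": drug, "administration": admin}


def _on_treatment_cycles(regimen: Regimen, n: int) -> np.ndarray:
    """Boolean mask of cycles during which the regimen still administers
    drug to progression-free patients (induction block, then maintenance
    until progression/cap)."""
    mask = np.zeros(n, dtype=bool)
    mask[: min(regimen.n_induction_doses, n)] = True
    if regimen.maintenance is not None:
        start = regimen.n_induction_doses
        stop = n
        if regimen.maintenance_max_cycles is not None:
            stop = min(n, start + regimen.maintenance_max_cycles)
        mask[start:stop] = True
    return mask


def accrue_total_cost(
    trace: CohortTrace,
    arm_cfg: ArmCostConfig,
    prices: PriceTable,
    cfg: ModelConfig | None = None,
) -> CostBreakdown:
    """Total discounted cost of one arm with its component breakdown.

    Drug/administration discounting uses the scheduled administration times
    (cycle starts for induction, cycle evaluation times for maintenance);
    state-occupancy costs and incident-event costs discount at the cycle
    evaluation times.
    """
    cfg = cfg or trace.cfg
    n = trace.n_cycles
    disc_eval = cfg.discount_factors(cfg.eval_times)
    disc_bound = cfg.discount_factors(cfg.boundary_times[:-1])
    pf_eval = trace.progression_free

    drug = 0.0
    admin = 0.0
    mgmt_on = 0.0
    for regimen, w in arm_cfg.regimens:
        d, a = _regimen_cycle_costs(trace, regimen, prices, cfg)
        # induction billed at cycle starts, maintenance at evaluation times
        n_ind = min(regimen.n_induction_doses, n)
        disc = disc_eval.copy()
        disc[:n_ind] = disc_bound[:n_ind]
        drug = drug + w * np.sum(d * disc, axis=-1)
        admin = admin + w * np.sum(a * disc, axis=-1)
        on_mask = _on_treatment_cycles(regimen, n)
        on_weeks = np.sum(pf_eval[..., on_mask] * disc_eval[on_mask], axis=-1) * WEEKS_PER_CYCLE
        mgmt_on = mgmt_on + w * prices.mgmt_pfd_on_tx_per_week * on_weeks

    mgmt_off = 0.0
    for regimen, w in arm_cfg.regimens:
        off_mask = ~_on_treatment_cycles(regimen, n)
        off_weeks = np.sum(pf_eval[..., off_mask] * disc_eval[off_mask], axis=-1) * WEEKS_PER_CYCLE
        mgmt_off = mgmt_off + w * prices.mgmt_pfd_off_tx_per_week * off_weeks

    if arm_cfg.bsc_mode == "one_time":
        bsc = prices.bsc * np.sum(trace.incident_progressions * disc_eval, axis=-1)
    else:
        bsc = prices.bsc * np.sum(trace.progressed * disc_eval, axis=-1)
    terminal = prices.terminal_care * np.sum(trace.incident_deaths * disc_eval, axis=-1)

    return CostBreakdown(
        drug=np.asarray(drug, dtype=float),
        administration=np.asarray(admin, dtype=float),
        management_on_treatment=np.asarray(mgmt_on, dtype=float),
        management_off_treatment=np.asarray(mgmt_off, dtype=float),
        bsc=np.asarray(bsc, dtype=float),
        terminal_care=np.asarray(terminal, dtype=float),
    )


def cost_breakdown_frame(breakdown: CostBreakdown) -> pd.DataFrame:
    """One-row tidy table of a scalar cost breakdown (for CSV export)."""
    return pd.DataFrame([{k: float(v) for k, v in breakdown.as_dict().items()}])
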