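"""Synthetic survival data emulating a digitized trial readout.

The source curves behind the model were published only as Kaplan-Meier
figures; this module generates stand-ins with known truth so the whole
reconstruction-and-fitting stage can be validated end to end: censored
patient-level data drawn from any of the parametric families under uniform
accrual with an administrative cutoff, product-limit estimates with
numbers-at-risk, digitized-curve fixtures on a coarse grid, and the bundled
parameter files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from lifelines import KaplanMeierFitter

from .parameters import load_parameters, load_subgroups
from .reconstruct import DigitizedCurve, PseudoIPD
from .survival import SurvivalSpec, quantile, survival

__all__ = [
    "SimulationRecipe",
    "simulate_ipd",
    "km_estimate",
    "digitize",
    "emit_parameter_fixtures",
]


@dataclass(frozen=True)
class SimulationRecipe:
    """Ground truth and study design for one simulated arm.

    Patients accrue uniformly over ``accrual_months``; everyone still alive
    at ``cutoff_months`` after study start is administratively censored, so
    follow-up is staggered the way a real trial's would be.  ``seed`` is
    mandatory: no global RNG state is touched.
    """

    spec: SurvivalSpec
    n_subjects: int
    seed: int
    accrual_months: float = 12.0
    cutoff_months: float = np.inf

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.cutoff_months <= 0:
            raise ValueError("administrative cutoff must be positive")
        if self.accrual_months < 0:
            raise ValueError("accrual window must be non-negative")
        if np.isfinite(self.cutoff_months) and self.cutoff_months <= self.accrual_months:
            raise ValueError("cutoff must exceed the accrual window")


def simulate_ipd(recipe: SimulationRecipe) -> PseudoIPD:
    """Draw censored patient-level records from the recipe's truth.

    Event times come from the inverse CDF; an improper survival family
    (Gompertz with negative shape) yields infinite event times past its
    plateau, which are censored administratively.
    """
    rng = np.random.default_rng(recipe.seed)
    u = rng.uniform(size=recipe.n_subjects)
    plateau = float(survival(1e9, recipe.spec)) if not recipe.spec.is_proper() else 0.0
    t_event = np.full(recipe.n_subjects, np.inf)
    finite = u < 1 - plateau if plateau > 0 else np.ones(recipe.n_subjects, bool)
    t_event[finite] = np.asarray(quantile(u[finite], recipe.spec), dtype=float)

    entry = rng.uniform(0.0, recipe.accrual_months, size=recipe.n_subjects)
    follow_up = recipe.cutoff_months - entry
    observed = t_event <= follow_up
    times = np.where(observed, t_event, follow_up)
    if not np.all(np.isfinite(times)):
        raise ValueError(
            "infinite follow-up with an improper survival family; set a finite cutoff"
        )
    return PseudoIPD(times=times, events=observed.astype(int))


def _n_at_risk(ipd: PseudoIPD, at_times, snap_grid=None) -> np.ndarray:
    """At-risk counts.  With ``snap_grid`` set, event times are first
    rounded up to the grid, so the counts describe the same step process as
    a curve digitized on that grid (events between grid points appear at
    the next grid coordinate); censoring times are never snapped."""
    times = np.asarray(ipd.times, dtype=float).copy()
    if snap_grid is not None:
        grid = np.asarray(snap_grid, dtype=float)
        ev = ipd.events.astype(bool)
        idx = np.minimum(np.searchsorted(grid, times[ev], side="left"), len(grid) - 1)
        times[ev] = grid[idx]
    return np.array([(times >= tt).sum() for tt in np.asarray(at_times)], dtype=int)


def km_estimate(ipd: PseudoIPD, grid=None) -> DigitizedCurve:
    """Product-limit estimate of an arm, packaged as a digitized curve.

    With ``grid=None`` the exact step function is returned (coordinates at
    time 0 and every distinct observed time); passing a time grid instead
    evaluates the step function there — emulating digitization at a coarse
    resolution — with the numbers-at-risk table on the same grid.
    """
    if len(ipd) < 1:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    if grid is None:
        times = np.concatenate([[0.0], np.unique(ipd.times)])
        snap = None
    else:
        times = np.asarray(grid, dtype=float)
        if times[0] != 0:
            times = np.concatenate([[0.0], times])
        snap = times
    surv = kmf.predict(times).to_numpy()
    surv = np.minimum.accumulate(np.clip(surv, 0.0, 1.0))
    surv[times == 0] = 1.0
    return DigitizedCurve(
        times=times,
        survival=surv,
        risk_times=times,
        n_risk=_n_at_risk(ipd, times, snap_grid=snap),
        n_total=len(ipd),
    )


def digitize(ipd: PseudoIPD, n_points: int = 40, t_max: float | None = None) -> DigitizedCurve:
    """Digitized-curve fixture: the KM estimate read off at ``n_points``
    equally spaced times up to the last observed time."""
    t_max = float(np.max(ipd.times)) if t_max is None else t_max
    grid = np.linspace(0.0, t_max, n_points)
    return km_estimate(ipd, grid=grid)


def emit_parameter_fixtures(outdir) -> dict:
    """Write the bundled parameter table and subgroup hazard-ratio table
    under ``outdir/data`` and return the paths; both files round-trip
    through their readers."""
    outdir = Path(outdir) / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    params_path = outdir / "parameters.json"
    load_parameters().to_json(params_path)
    subgroups_path = outdir / "subgroups.csv"
    load_subgroups().to_csv(subgroups_path, index=False)
    return {"parameters": params_path, "subgroups": subgroups_path}
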