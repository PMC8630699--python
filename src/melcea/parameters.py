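"""Model parameter set: baselines, uncertainty ranges and PSA families.

The bundled parameter file transcribes the published model inputs: the
fitted log-logistic OS/PFS curves of the ipilimumab arm, the combination
arm's hazard ratios with 95% CIs, treatment-response shares, health-state
utilities and all unit costs, each with its range (95% CI or ±20%) and the
distribution family used in probabilistic sensitivity analysis.  The
survival-curve parameters carry no distribution and stay fixed in the PSA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .survival import SurvivalSpec

__all__ = ["Parameter", "ParameterSet", "load_parameters", "load_subgroups"]

DISTRIBUTIONS = ("gamma", "lognormal", "beta", "fixed")


@dataclass(frozen=True)
class Parameter:
    """One scalar model input with its baseline, range and PSA family."""

    name: str
    baseline: float
    low: float
    high: float
    distribution: str
    label: str = ""

    def __post_init__(self):
        if not (self.low <= self.baseline <= self.high):
            raise ValueError(
                f"{self.name}: baseline {self.baseline} outside [{self.low}, {self.high}]"
            )
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")

    @property
    def is_fixed(self) -> bool:
        return self.distribution == "fixed" or self.low == self.high


class ParameterSet:
    """All model inputs: two baseline survival specs plus the scalar
    parameters, with dict-style access to baselines by name."""

    def __init__(self, survival: dict, parameters: dict, settings: dict):
        self.survival = dict(survival)
        self.parameters = dict(parameters)
        self.settings = dict(settings)
        for key in ("os_ipilimumab", "pfs_ipilimumab"):
            if key not in self.survival:
                raise ValueError(f"missing survival spec {key!r}")

    @property
    def os_spec(self) -> SurvivalSpec:
        return self.survival["os_ipilimumab"]

    @property
    def pfs_spec(self) -> SurvivalSpec:
        return self.survival["pfs_ipilimumab"]

    def baseline_values(self) -> dict:
        return {name: p.baseline for name, p in self.parameters.items()}

    def __getitem__(self, name: str) -> Parameter:
        return self.parameters[name]

    def __iter__(self):
        return iter(self.parameters.values())

    def __len__(self):
        return len(self.parameters)

    def replace_parameter(self, name: str, **changes) -> "ParameterSet":
        """Return a copy with one parameter's fields replaced."""
        p = self.parameters[name]
        new = Parameter(
            name=name,
            baseline=changes.get("baseline", p.baseline),
            low=changes.get("low", p.low),
            high=changes.get("high", p.high),
            distribution=changes.get("distribution", p.distribution),
            label=changes.get("label", p.label),
        )
        params = dict(self.parameters)
        params[name] = new
        return ParameterSet(self.survival, params, self.settings)

    def to_dict(self) -> dict:
        return {
            "survival": {
                name: {
                    "family": spec.family,
                    "params": list(spec.params),
                    "time_unit": spec.time_unit,
                }
                for name, spec in self.survival.items()
            },
            "parameters": {
                name: {
                    "baseline": p.baseline,
                    "min": p.low,
                    "max": p.high,
                    "distribution": p.distribution,
                    "label": p.label,
                }
                for name, p in self.parameters.items()
            },
            "settings": dict(self.settings),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, doc: dict) -> "ParameterSet":
        survival = {
            name: SurvivalSpec(
                family=entry["family"],
                params=tuple(entry["params"]),
                time_unit=entry.get("time_unit", "months"),
            )
            for name, entry in doc["survival"].items()
        }
        parameters = {
            name: Parameter(
                name=name,
                baseline=float(entry["baseline"]),
                low=float(entry["min"]),
                high=float(entry["max"]),
                distribution=entry["distribution"],
                label=entry.get("label", ""),
            )
            for name, entry in doc["parameters"].items()
        }
        return cls(survival, parameters, doc.get("settings", {}))

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_parameters(path=None) -> ParameterSet:
    """Load the bundled published parameter table (or a user file)."""
    if path is not None:
        return ParameterSet.from_json(path)
    text = resources.files("melcea.data").joinpath("parameters.json").read_text()
    return ParameterSet.from_dict(json.loads(text))


def load_subgroups(path=None) -> pd.DataFrame:
    """Load the subgroup hazard-ratio table (PFS and OS HR with 95% CIs
    per pre-specified subgroup)."""
    if path is not None:
        return pd.read_csv(path)
    with resources.files("melcea.data").joinpath("subgroups.csv").open() as fh:
        return pd.read_csv(fh)
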