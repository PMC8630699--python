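"""Closed-form parametric survival families and hazard-ratio adjustment.

Six candidate families are supported for extrapolating progression-free and
overall survival beyond trial follow-up: exponential, Weibull, lognormal,
log-logistic, Gompertz and generalized gamma.  All work in months.

The log-logistic family uses the odds parameterization

    S(t) = 1 / (1 + theta * t**kappa),    theta > 0, kappa > 0,

so that ``theta * t**kappa`` is the odds of having died by ``t`` and the
median is ``theta**(-1/kappa)``.  The generalized gamma uses the log-time
(mu, sigma, Q) parameterization, which nests the lognormal at Q=0 and the
Weibull at Q=1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "FAMILIES",
    "N_PARAMS",
    "SurvivalSpec",
    "survival",
    "hazard",
    "density",
    "quantile",
    "apply_hazard_ratio",
]

FAMILIES = (
    "exponential",
    "weibull",
    "lognormal",
    "loglogistic",
    "gompertz",
    "generalized_gamma",
)

N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "lognormal": 2,
    "loglogistic": 2,
    "gompertz": 2,
    "generalized_gamma": 3,
}

_EPS = 1e-300


@dataclass(frozen=True)
class SurvivalSpec:
    """A parametric survival model: family name plus parameter vector.

    Parameters by family (time in months):

    - exponential: (rate,), rate > 0
    - weibull: (shape, scale), both > 0; S(t) = exp(-(t/scale)**shape)
    - lognormal: (mu, sigma), sigma > 0 on log-time
    - loglogistic: (theta, kappa), both > 0; S(t) = 1/(1 + theta*t**kappa)
    - gompertz: (shape, rate), rate > 0; shape may be negative (improper
      survival with a plateau, flagged by :meth:`is_proper`)
    - generalized_gamma: (mu, sigma, Q), sigma > 0
    """

    family: str
    params: tuple = field(default_factory=tuple)
    time_unit: str = "months"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if len(self.params) != N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} needs {N_PARAMS[self.family]} parameters, "
                f"got {len(self.params)}"
            )
        if self.time_unit != "months":
            raise ValueError("only months are supported as the working time unit")
        _validate_params(self.family, self.params)

    def survival(self, t):
        return survival(t, self)

    def hazard(self, t):
        return hazard(t, self)

    def density(self, t):
        return density(t, self)

    def quantile(self, p):
        return quantile(p, self)

    @property
    def median(self) -> float:
        return float(self.quantile(0.5))

    def is_proper(self) -> bool:
        """Whether S(t) -> 0 as t -> infinity (Gompertz with negative shape
        plateaus above zero and is flagged improper)."""
        if self.family == "gompertz" and self.params[0] < 0:
            return False
        return True


def _validate_params(family: str, p: tuple) -> None:
    if family == "exponential":
        if p[0] <= 0:
            raise ValueError("exponential rate must be > 0")
    elif family == "weibull":
        if p[0] <= 0 or p[1] <= 0:
            raise ValueError("weibull shape and scale must be > 0")
    elif family == "lognormal":
        if p[1] <= 0:
            raise ValueError("lognormal sigma must be > 0")
    elif family == "loglogistic":
        if p[0] <= 0 or p[1] <= 0:
            raise ValueError("loglogistic theta and kappa must be > 0")
    elif family == "gompertz":
        if p[1] <= 0:
            raise ValueError("gompertz rate must be > 0")
    elif family == "generalized_gamma":
        if p[1] <= 0:
            raise ValueError("generalized gamma sigma must be > 0")


def _check_time(t, allow_zero: bool = True):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if not allow_zero and np.any(t == 0):
        raise ValueError("time must be strictly positive")
    return t


def log_survival(t, spec: SurvivalSpec):
    """log S(t), vectorized; finite for t >= 0 wherever S > 0."""
    t = _check_time(t)
    p = spec.params
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if spec.family == "exponential":
            out = -p[0] * t
        elif spec.family == "weibull":
            out = -((t / p[1]) ** p[0])
        elif spec.family == "lognormal":
            out = np.where(
                t > 0,
                norm.logsf((np.log(np.maximum(t, _EPS)) - p[0]) / p[1]),
                0.0,
            )
        elif spec.family == "loglogistic":
            out = -np.log1p(p[0] * t ** p[1])
        elif spec.family == "gompertz":
            a, b = p
            if abs(a) < 1e-12:
                out = -b * t
            else:
                out = -(b / a) * np.expm1(a * t)
        elif spec.family == "generalized_gamma":
            out = np.where(t > 0, np.log(np.maximum(_gg_sf(t, *p), _EPS)), 0.0)
        else:  # pragma: no cover
            raise AssertionError
    return out


def _gg_sf(t, mu, sigma, Q):
    """Generalized-gamma survival, (mu, sigma, Q) log-time parameterization."""
    t = np.maximum(np.asarray(t, dtype=float), _EPS)
    w = (np.log(t) - mu) / sigma
    if abs(Q) < 1e-8:
        return norm.sf(w)
    a = Q ** -2
    u = a * np.exp(Q * w)
    if Q > 0:
        return special.gammaincc(a, u)
    return special.gammainc(a, u)


def survival(t, spec: SurvivalSpec):
    """S(t) in [0, 1]; S(0) = 1 for every family."""
    return np.exp(log_survival(t, spec))


def log_density(t, spec: SurvivalSpec):
    """log f(t) for t > 0, vectorized (used by the censored likelihood)."""
    t = _check_time(t, allow_zero=False)
    p = spec.params
    if spec.family == "exponential":
        return np.log(p[0]) - p[0] * t
    if spec.family == "weibull":
        k, lam = p
        return np.log(k / lam) + (k - 1) * np.log(t / lam) - (t / lam) ** k
    if spec.family == "lognormal":
        mu, s = p
        z = (np.log(t) - mu) / s
        return -0.5 * z**2 - np.log(t * s * np.sqrt(2 * np.pi))
    if spec.family == "loglogistic":
        th, ka = p
        return (
            np.log(th * ka)
            + (ka - 1) * np.log(t)
            - 2 * np.log1p(th * t**ka)
        )
    if spec.family == "gompertz":
        a, b = p
        if abs(a) < 1e-12:
            return np.log(b) - b * t
        return np.log(b) + a * t - (b / a) * np.expm1(a * t)
    if spec.family == "generalized_gamma":
        mu, s, Q = p
        w = (np.log(t) - mu) / s
        if abs(Q) < 1e-8:
            return -0.5 * w**2 - np.log(t * s * np.sqrt(2 * np.pi))
        a = Q ** -2
        return (
            np.log(abs(Q))
            + a * np.log(a)
            - special.gammaln(a)
            + a * (Q * w - np.exp(Q * w))
            - np.log(s * t)
        )
    raise AssertionError  # pragma: no cover


def density(t, spec: SurvivalSpec):
    return np.exp(log_density(t, spec))


def hazard(t, spec: SurvivalSpec):
    """Instantaneous hazard h(t) = f(t)/S(t), per month, for t > 0."""
    t = _check_time(t, allow_zero=False)
    return np.exp(log_density(t, spec) - log_survival(t, spec))


def quantile(p, spec: SurvivalSpec):
    """Inverse CDF: smallest t with F(t) >= p.  Closed form where available,
    bracketed root-finding otherwise."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr >= 1)):
        raise ValueError("probability must lie in [0, 1)")
    pars = spec.params
    if spec.family == "exponential":
        return -np.log1p(-p_arr) / pars[0]
    if spec.family == "weibull":
        k, lam = pars
        return lam * (-np.log1p(-p_arr)) ** (1 / k)
    if spec.family == "lognormal":
        mu, s = pars
        return np.exp(mu + s * norm.ppf(p_arr))
    if spec.family == "loglogistic":
        th, ka = pars
        return (p_arr / ((1 - p_arr) * th)) ** (1 / ka)
    if spec.family == "gompertz":
        a, b = pars
        if abs(a) < 1e-12:
            return -np.log1p(-p_arr) / b
        arg = 1 - (a / b) * np.log1p(-p_arr)
        if np.any(arg <= 0):
            raise ValueError(
                "quantile beyond the plateau of an improper Gompertz survival"
            )
        return np.log(arg) / a
    # generalized gamma: numeric inversion of the closed-form CDF
    def _one(prob):
        if prob == 0:
            return 0.0
        f = lambda t: (1.0 - _gg_sf(t, *pars)) - prob
        hi = 1.0
        while f(hi) < 0:
            hi *= 2
            if hi > 1e12:  # pragma: no cover
                raise RuntimeError("quantile bracketing failed")
        return brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-12)

    return np.vectorize(_one)(p_arr)


def apply_hazard_ratio(
    spec: SurvivalSpec, hr, mode: str = "ph"
) -> Callable:
    """Return the adjusted survival function of a comparator arm.

    mode='ph' (default): proportional hazards on the fitted baseline,
    S1(t) = S0(t)**hr, i.e. the cumulative hazard is scaled by ``hr``.
    mode='aft': accelerated failure time, S1(t) = S0(hr * t) (a protective
    hr < 1 slows the passage of disease time).

    ``hr`` may be an array; the returned callable broadcasts it against a
    leading axis, so ``fn(t)`` has shape ``hr.shape + t.shape``.
    """
    hr_arr = np.asarray(hr, dtype=float)
    if np.any(hr_arr <= 0):
        raise ValueError("hazard ratio must be > 0")
    if mode not in ("ph", "aft"):
        raise ValueError(f"unknown hazard-ratio mode {mode!r}")

    if mode == "ph":

        def fn(t):
            logs = log_survival(t, spec)
            if hr_arr.ndim == 0:
                return np.exp(hr_arr * logs)
            return np.exp(hr_arr.reshape(hr_arr.shape + (1,) * np.ndim(logs)) * logs)

    else:

        def fn(t):
            t = np.asarray(t, dtype=float)
            if hr_arr.ndim == 0:
                return survival(hr_arr * t, spec)
            scaled = hr_arr.reshape(hr_arr.shape + (1,) * t.ndim) * t
            return survival(scaled, spec)

    return fn
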