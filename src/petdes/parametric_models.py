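"""Parametric time-to-event machinery.

Every fitted prediction equation in the model is stored as an
:class:`EquationSpec` — a named coefficient vector plus a distribution family
and dispersion parameter — and evaluated against a covariate map.  Three
stochastic families are used:

* lognormal AFT: ``T = exp(mu + sigma * Z)`` with ``mu`` the linear predictor;
* Weibull AFT: ``T = exp(mu) * (-ln U) ** sigma`` under the default
  sigma-interpretation of the printed dispersion (``S(t) =
  exp(-(t/exp(mu))**(1/sigma))``), or shape-``k`` with ``T = exp(mu) *
  (-ln U) ** (1/k)`` when configured;
* Weibull rate form for dementia conversion: ``S(t) = exp(-lam * t**k)``
  (alternative scale-inside-power form ``S(t) = exp(-(lam*t)**k)``);
* Gompertz age-based mortality: hazard ``h(a) = hr * exp(scale + shape*a)``
  with residual lifetimes sampled conditional on survival to the current age.

Closed-form means/medians are provided alongside the samplers so simulated
output can always be checked against analytic values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "EquationSpec",
    "linear_predictor",
    "sample_lognormal_aft",
    "lognormal_mean",
    "lognormal_median",
    "sample_weibull_aft",
    "weibull_aft_median",
    "sample_weibull_rate",
    "weibull_rate_median",
    "gompertz_hazard",
    "gompertz_cumulative_hazard",
    "sample_gompertz_residual",
    "median_of",
]

_TINY = 1e-300


class MissingCovariateError(KeyError):
    pass


@dataclass
class EquationSpec:
    """One fitted equation: linear predictor terms + distribution family.

    ``dispersion`` is the log-scale SD for ``lognormal_aft``, the printed
    dispersion ("SD/shape") for ``weibull_aft``, the Weibull shape for
    ``weibull_rate`` and the Gompertz shape for ``gompertz``.  ``rate`` is the
    scale parameter of the rate-form Weibull.  ``post_multiplier`` rescales
    the whole linear predictor (used by the behaviour-scale equation).
    """

    name: str
    family: str
    intercept: float = 0.0
    terms: dict[str, float] = field(default_factory=dict)
    dispersion: float | None = None
    rate: float | None = None
    post_multiplier: float = 1.0
    time_unit: str = "days"

    def __post_init__(self) -> None:
        known = {"lognormal_aft", "weibull_aft", "weibull_rate", "gompertz", "linear"}
        if self.family not in known:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family != "linear" and (self.dispersion is None or self.dispersion <= 0):
            raise ValueError(f"equation {self.name!r}: dispersion must be > 0")

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "EquationSpec":
        return cls(
            name=name,
            family=d["family"],
            intercept=d.get("intercept", 0.0),
            terms=dict(d.get("terms", {})),
            dispersion=d.get("dispersion"),
            rate=d.get("rate"),
            post_multiplier=d.get("post_multiplier", 1.0),
            time_unit=d.get("time_unit", "days"),
        )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "intercept": self.intercept,
            "terms": dict(self.terms),
            "dispersion": self.dispersion,
            "rate": self.rate,
            "post_multiplier": self.post_multiplier,
            "time_unit": self.time_unit,
        }


def linear_predictor(spec: EquationSpec, covariates: Mapping[str, float]) -> float:
    """``intercept + sum(coef * value)``, times any post-multiplier."""
    total = spec.intercept
    for name, coef in spec.terms.items():
        try:
            total += coef * float(covariates[name])
        except KeyError:
            raise MissingCovariateError(
                f"equation {spec.name!r} needs covariate {name!r}"
            ) from None
    return total * spec.post_multiplier


# ---------------------------------------------------------------------------
# Lognormal AFT
# ---------------------------------------------------------------------------

def sample_lognormal_aft(mu: float, sigma: float, rng: np.random.Generator,
                         size: int | None = None):
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    z = rng.standard_normal(size)
    return np.exp(mu + sigma * z)


def lognormal_mean(mu: float, sigma: float) -> float:
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return math.exp(mu + 0.5 * sigma * sigma)


def lognormal_median(mu: float) -> float:
    return math.exp(mu)


# ---------------------------------------------------------------------------
# Weibull AFT
# ---------------------------------------------------------------------------

def sample_weibull_aft(mu: float, shape_param: float, rng: np.random.Generator,
                       size: int | None = None, *, shape_is_sigma: bool = True):
    """Accelerated-failure-time Weibull draw.

    Under the default sigma-interpretation ``T = exp(mu) * (-ln U)**sigma``;
    under the k-interpretation ``T = exp(mu) * (-ln U)**(1/k)``.
    """
    if shape_param <= 0:
        raise ValueError("shape parameter must be > 0")
    expo = shape_param if shape_is_sigma else 1.0 / shape_param
    u = rng.uniform(size=size)
    return np.exp(mu) * (-np.log(np.maximum(u, _TINY))) ** expo


def weibull_aft_median(mu: float, shape_param: float, *, shape_is_sigma: bool = True) -> float:
    expo = shape_param if shape_is_sigma else 1.0 / shape_param
    return math.exp(mu) * math.log(2.0) ** expo


# ---------------------------------------------------------------------------
# Weibull rate form (conversion to dementia)
# ---------------------------------------------------------------------------

def sample_weibull_rate(lam: float, k: float, rng: np.random.Generator,
                        size: int | None = None, *, param: str = "rate"):
    """Draw from ``S(t) = exp(-lam * t**k)`` (``param="rate"``) or
    ``S(t) = exp(-(lam*t)**k)`` (``param="scale_power"``)."""
    if lam <= 0 or k <= 0:
        raise ValueError("lam and k must be > 0")
    u = rng.uniform(size=size)
    h = -np.log(np.maximum(u, _TINY))
    if param == "rate":
        return (h / lam) ** (1.0 / k)
    if param == "scale_power":
        return h ** (1.0 / k) / lam
    raise ValueError(f"unknown conversion parameterization {param!r}")


def weibull_rate_median(lam: float, k: float, *, param: str = "rate") -> float:
    if param == "rate":
        return (math.log(2.0) / lam) ** (1.0 / k)
    if param == "scale_power":
        return math.log(2.0) ** (1.0 / k) / lam
    raise ValueError(f"unknown conversion parameterization {param!r}")


# ---------------------------------------------------------------------------
# Gompertz mortality
# ---------------------------------------------------------------------------

def gompertz_hazard(scale: float, shape: float, age: float, hr: float = 1.0) -> float:
    """Instantaneous yearly hazard ``hr * exp(scale + shape * age)``."""
    if shape <= 0:
        raise ValueError("shape must be > 0")
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    return hr * math.exp(scale + shape * age)


def gompertz_cumulative_hazard(scale: float, shape: float, age0: float, t: float,
                               hr: float = 1.0) -> float:
    """Cumulative hazard accrued between ``age0`` and ``age0 + t`` (years)."""
    return hr * math.exp(scale) / shape * (
        math.exp(shape * (age0 + t)) - math.exp(shape * age0)
    )


def _gompertz_inverse(scale: float, shape: float, age0: float, h: float,
                      hr: float = 1.0) -> float:
    """Residual time ``t`` with ``gompertz_cumulative_hazard(..., t) == h``."""
    inner = h * shape / (hr * math.exp(scale)) + math.exp(shape * age0)
    return math.log(inner) / shape - age0


def sample_gompertz_residual(scale: float, shape: float, current_age: float,
                             hr: float, rng: np.random.Generator,
                             size: int | None = None, *, min_age: float = 55.0):
    """Residual years of life conditional on survival to ``current_age``.

    Inverse-CDF sampling: the conditional survival is
    ``exp(-(Lambda(a0 + t) - Lambda(a0)))`` so ``t`` solves the cumulative
    hazard equation at ``-ln U``.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    if shape <= 0:
        raise ValueError("shape must be > 0")
    if current_age < min_age:
        raise ValueError(f"age {current_age} below the life-table basis ({min_age})")
    u = rng.uniform(size=size)
    h = -np.log(np.maximum(u, _TINY))
    if size is None:
        return _gompertz_inverse(scale, shape, current_age, float(h), hr)
    return np.array([_gompertz_inverse(scale, shape, current_age, hi, hr) for hi in np.atleast_1d(h)])


# ---------------------------------------------------------------------------
# Analytic medians
# ---------------------------------------------------------------------------

def median_of(spec: EquationSpec, covariates: Mapping[str, float] | None = None,
              *, shape_is_sigma: bool = True, param: str = "rate") -> float:
    """Closed-form median of the event-time distribution of ``spec``."""
    covariates = covariates or {}
    if spec.family == "lognormal_aft":
        return lognormal_median(linear_predictor(spec, covariates))
    if spec.family == "weibull_aft":
        return weibull_aft_median(linear_predictor(spec, covariates),
                                  spec.dispersion, shape_is_sigma=shape_is_sigma)
    if spec.family == "weibull_rate":
        return weibull_rate_median(spec.rate, spec.dispersion, param=param)
    raise ValueError(f"no closed-form median for family {spec.family!r}")
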