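"""Six classical nonlinear growth functions and their analytic machinery.

Each model describes mean body weight W(t) (kg) as a function of age t (days)
through at most four parameters:

* ``alpha`` — asymptotic (mature) weight, kg; W(t) → alpha as t → ∞.
* ``beta``  — dimensionless scale tied to the birth weight (e.g. the MMF
  curve starts exactly at W(0) = beta, the Weibull at alpha − beta).
* ``k``     — maturation-rate constant, per day.
* ``m``     — shape parameter of the flexible-inflection families (MMF,
  Weibull); m > 1 yields a sigmoid with an interior inflection point.

The module provides the mean curves (:func:`predict`), their analytic first
derivatives — the absolute growth rate, AGR, in kg/day (:func:`agr`) — and
closed-form inflection points where they exist (:func:`inflection`).  The
additive observation error does not live here: these are the deterministic
mean functions used by least squares.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ModelFamily",
    "ParamSet",
    "ModelValidationError",
    "param_names",
    "n_params",
    "predict",
    "agr",
    "inflection",
]


class ModelValidationError(ValueError):
    """Raised when a parameter set violates a model's constraints."""


class ModelFamily(str, enum.Enum):
    """The six growth-curve families.

    Mean functions (error term excluded):

    ==================== ===========================================
    negative_exponential W(t) = alpha * (1 - exp(-k t))
    brody                W(t) = alpha * (1 - beta exp(-k t))
    gompertz             W(t) = alpha * exp(-beta exp(-k t))
    logistic             W(t) = alpha / (1 + beta exp(-k t))
    mmf                  W(t) = alpha - (alpha - beta) / (1 + (k t)^m)
    weibull              W(t) = alpha - beta exp(-k t^m)
    ==================== ===========================================
    """

    NEGATIVE_EXPONENTIAL = "negative_exponential"
    BRODY = "brody"
    GOMPERTZ = "gompertz"
    LOGISTIC = "logistic"
    MMF = "mmf"
    WEIBULL = "weibull"

    @classmethod
    def coerce(cls, value: "ModelFamily | str") -> "ModelFamily":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ModelValidationError(
                f"unknown model {value!r}; valid names: {valid}"
            ) from None


#: Parameter names used by each family, in canonical order.
_PARAMS = {
    ModelFamily.NEGATIVE_EXPONENTIAL: ("alpha", "k"),
    ModelFamily.BRODY: ("alpha", "beta", "k"),
    ModelFamily.GOMPERTZ: ("alpha", "beta", "k"),
    ModelFamily.LOGISTIC: ("alpha", "beta", "k"),
    ModelFamily.MMF: ("alpha", "beta", "k", "m"),
    ModelFamily.WEIBULL: ("alpha", "beta", "k", "m"),
}

#: Families with a flexible shape parameter m.
SHAPE_MODELS = frozenset({ModelFamily.MMF, ModelFamily.WEIBULL})


def param_names(model: ModelFamily | str) -> tuple[str, ...]:
    """Canonical parameter names for *model*."""
    return _PARAMS[ModelFamily.coerce(model)]


def n_params(model: ModelFamily | str) -> int:
    """Number of curve parameters (2 for negative exponential, 3 for
    Brody/Gompertz/Logistic, 4 for MMF/Weibull)."""
    return len(param_names(model))


@dataclass(frozen=True)
class ParamSet:
    """A growth-curve parameter set.

    ``beta`` and ``m`` are ``None`` for families that do not use them.
    All present parameters must be strictly positive.  For the MMF family
    ``beta < alpha`` is required (the curve starts at beta and rises to
    alpha).  Brody values of beta above 1 imply a negative birth weight and
    draw a warning rather than an error: they can arise transiently during
    optimisation and fitted values stay at or just below 1 in practice.
    """

    alpha: float
    k: float
    beta: Optional[float] = None
    m: Optional[float] = None

    def values_for(self, model: ModelFamily | str) -> tuple[float, ...]:
        """Parameter values in the canonical order of *model*."""
        return tuple(getattr(self, p) for p in param_names(model))

    def as_dict(self, model: ModelFamily | str) -> dict[str, float]:
        return dict(zip(param_names(model), self.values_for(model)))

    @classmethod
    def from_values(
        cls, model: ModelFamily | str, values: "np.ndarray | tuple"
    ) -> "ParamSet":
        names = param_names(model)
        if len(values) != len(names):
            raise ModelValidationError(
                f"{ModelFamily.coerce(model).value} takes {len(names)} "
                f"parameters {names}, got {len(values)}"
            )
        return cls(**dict(zip(names, (float(v) for v in values))))


def validate_params(model: ModelFamily | str, theta: ParamSet) -> None:
    """Raise :class:`ModelValidationError` if *theta* is invalid for *model*."""
    model = ModelFamily.coerce(model)
    for name in param_names(model):
        value = getattr(theta, name)
        if value is None:
            raise ModelValidationError(
                f"{model.value} requires parameter {name!r}"
            )
        if not math.isfinite(value) or value <= 0:
            raise ModelValidationError(
                f"{model.value} parameter {name}={value!r} must be finite and > 0"
            )
    if model is ModelFamily.MMF and theta.beta >= theta.alpha:
        raise ModelValidationError(
            f"mmf requires beta < alpha (birth weight below the asymptote); "
            f"got beta={theta.beta}, alpha={theta.alpha}"
        )
    if model is ModelFamily.BRODY and theta.beta > 1.0:
        warnings.warn(
            f"brody beta={theta.beta:.4g} > 1 implies a negative weight at "
            "birth; the curve is still defined but check the fit",
            stacklevel=3,
        )


def _check_age(t: "np.ndarray | float") -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be non-negative (days since birth)")
    return t


def predict(
    model: ModelFamily | str, theta: ParamSet, t: "np.ndarray | float"
) -> "np.ndarray | float":
    """Mean body weight (kg) of *model* at age(s) *t* (days).

    Vectorised over ``t``; returns a scalar for scalar input.
    """
    model = ModelFamily.coerce(model)
    validate_params(model, theta)
    t = _check_age(t)
    a, b, k, m = theta.alpha, theta.beta, theta.k, theta.m

    if model is ModelFamily.NEGATIVE_EXPONENTIAL:
        w = a * (1.0 - np.exp(-k * t))
    elif model is ModelFamily.BRODY:
        w = a * (1.0 - b * np.exp(-k * t))
    elif model is ModelFamily.GOMPERTZ:
        w = a * np.exp(-b * np.exp(-k * t))
    elif model is ModelFamily.LOGISTIC:
        w = a / (1.0 + b * np.exp(-k * t))
    elif model is ModelFamily.MMF:
        w = a - (a - b) / (1.0 + (k * t) ** m)
    else:  # weibull
        w = a - b * np.exp(-k * t**m)
    return w if w.ndim else float(w)


def agr(
    model: ModelFamily | str, theta: ParamSet, t: "np.ndarray | float"
) -> "np.ndarray | float":
    """Absolute growth rate dW/dt (kg/day) at age(s) *t*.

    Analytic derivative of the mean curve.  At ``t = 0`` the shape families
    involve the limit of ``t**(m-1)``: zero when ``m > 1``, the finite value
    ``(alpha-beta)*k`` (MMF) or ``beta*k`` (Weibull) when ``m == 1``, and
    ``+inf`` (with a warning) when ``m < 1``.
    """
    model = ModelFamily.coerce(model)
    validate_params(model, theta)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(_check_age(t))
    a, b, k, m = theta.alpha, theta.beta, theta.k, theta.m

    if model is ModelFamily.NEGATIVE_EXPONENTIAL:
        r = a * k * np.exp(-k * t)
    elif model is ModelFamily.BRODY:
        r = a * b * k * np.exp(-k * t)
    elif model is ModelFamily.GOMPERTZ:
        e = b * np.exp(-k * t)
        r = a * k * e * np.exp(-e)
    elif model is ModelFamily.LOGISTIC:
        e = b * np.exp(-k * t)
        r = a * k * e / (1.0 + e) ** 2
    else:
        r = _shape_agr(model, a, b, k, m, t)

    r = np.asarray(r, dtype=float)
    return float(r[0]) if scalar else r


def _shape_agr(model, a, b, k, m, t):
    # t^(m-1) needs explicit limits at t=0 depending on m.
    with np.errstate(divide="ignore"):
        tp = np.where(t > 0, t, 1.0) ** (m - 1.0)
    if model is ModelFamily.MMF:
        r = (a - b) * m * k**m * tp / (1.0 + (k * np.where(t > 0, t, 0.0)) ** m) ** 2
    else:  # weibull
        r = b * k * m * tp * np.exp(-k * np.where(t > 0, t, 0.0) ** m)
    at_zero = t == 0
    if np.any(at_zero):
        if m > 1:
            r = np.where(at_zero, 0.0, r)
        elif m == 1:
            r0 = (a - b) * k if model is ModelFamily.MMF else b * k
            r = np.where(at_zero, r0, r)
        else:
            warnings.warn(
                f"{model.value} AGR diverges at t=0 for m={m:.4g} < 1; "
                "reporting +inf",
                stacklevel=3,
            )
            r = np.where(at_zero, np.inf, r)
    return r


def inflection(
    model: ModelFamily | str, theta: ParamSet
) -> Optional[tuple[float, float]]:
    """Closed-form inflection point ``(t*, W(t*))`` or ``None``.

    The inflection is the age of maximal growth rate.  Gompertz and Logistic
    have fixed inflection weights (alpha/e and alpha/2); MMF and Weibull have
    an interior inflection only when m > 1.  The negative exponential and
    Brody curves are concave throughout (AGR strictly decreasing), so no
    inflection exists for t > 0.
    """
    model = ModelFamily.coerce(model)
    validate_params(model, theta)
    a, b, k, m = theta.alpha, theta.beta, theta.k, theta.m

    if model in (ModelFamily.NEGATIVE_EXPONENTIAL, ModelFamily.BRODY):
        return None
    if model is ModelFamily.GOMPERTZ:
        t_star = math.log(b) / k
        return (t_star, a / math.e) if t_star > 0 else None
    if model is ModelFamily.LOGISTIC:
        t_star = math.log(b) / k
        return (t_star, a / 2.0) if t_star > 0 else None
    if m <= 1.0:
        return None
    if model is ModelFamily.MMF:
        # d/dt log AGR = 0  <=>  (kt)^m = (m-1)/(m+1)
        t_star = ((m - 1.0) / (m + 1.0)) ** (1.0 / m) / k
    else:  # weibull: t^m = (m-1)/(k m)
        t_star = ((m - 1.0) / (k * m)) ** (1.0 / m)
    return t_star, float(predict(model, theta, t_star))
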