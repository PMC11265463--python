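"""Nonlinear least-squares estimation of growth-curve parameters.

A pooled fit: all records of a group enter a single sum of squared errors
SSE = Σ_i (W_i − W(t_i; θ))², with no per-animal random effects.  Parameters
are estimated by Levenberg–Marquardt damped least squares on log-transformed
parameters, which enforces positivity by construction while behaving like an
unconstrained solver.  Self-starting values come from linearising each mean
curve on the age-binned weight profile; MMF and Weibull additionally grid
over the shape parameter m.  Asymptotic standard errors use the Gauss–Newton
approximation sigma² (JᵀJ)⁻¹ with sigma² = SSE/(n−p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .data_io import GrowthDataset
from .models import (
    ModelFamily,
    ParamSet,
    n_params,
    param_names,
    predict,
)

__all__ = [
    "FitResult",
    "DegenerateDataError",
    "InsufficientDataError",
    "initial_values",
    "fit",
    "standard_errors",
]

log = logging.getLogger(__name__)

MAX_ITER = 500
TOL_SSE = 1e-10  # relative SSE improvement
TOL_STEP = 1e-8  # parameter step


class DegenerateDataError(ValueError):
    """The data carry no growth signal (e.g. constant weights)."""


class InsufficientDataError(ValueError):
    """Too few distinct ages or records to identify the model."""


@dataclass
class FitResult:
    """Outcome of one pooled nonlinear least-squares fit."""

    model: ModelFamily
    group_label: str
    theta_hat: ParamSet
    se: Optional[dict[str, float]]  # None when unavailable (rank-deficient/dof)
    sse: float
    n_obs: int
    converged: bool
    n_iter: int
    sst: float = field(default=float("nan"))
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model.value,
            "group_label": self.group_label,
            "params": self.theta_hat.as_dict(self.model),
            "se": self.se,
            "sse": self.sse,
            "sst": self.sst,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "message": self.message,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        model = ModelFamily.coerce(d["model"])
        return cls(
            model=model,
            group_label=d["group_label"],
            theta_hat=ParamSet(**d["params"]),
            se=d.get("se"),
            sse=float(d["sse"]),
            sst=float(d.get("sst", float("nan"))),
            n_obs=int(d["n_obs"]),
            converged=bool(d["converged"]),
            n_iter=int(d.get("n_iter", 0)),
            message=d.get("message", ""),
        )


# ---------------------------------------------------------------------------
# self-starting values
# ---------------------------------------------------------------------------


def _binned_means(ds: GrowthDataset) -> tuple[np.ndarray, np.ndarray]:
    grouped = ds.df.groupby("age_days")["weight_kg"].mean()
    return grouped.index.to_numpy(dtype=float), grouped.to_numpy(dtype=float)


#: candidate asymptote multipliers: the true mature weight may sit well
#: above the heaviest weight observed in a window that ends mid-growth
ALPHA_MULTIPLIERS = (1.05, 1.2, 1.5, 2.0, 3.0)


def initial_values(model: ModelFamily | str, ds: GrowthDataset) -> ParamSet:
    """Self-starting parameter values from linearised regressions.

    Candidate asymptotes alpha0 = c * max(W) are tried for a small ladder of
    multipliers c (1.05 up to 3: a window ending mid-growth can hide an
    asymptote far above the heaviest observed weight).  For each candidate
    the remaining parameters come from linearising the mean curve on the
    age-binned weight profile (e.g. Gompertz: ln(-ln(W/alpha0)) is linear in
    t with slope -k and intercept ln beta); bins within 10% of alpha0 are
    excluded because the transforms blow up there.  MMF/Weibull instead
    start beta from the earliest-age mean and grid over the shape m in
    {0.5, 0.75, ..., 3.0} with k profiled on a log-spaced grid.  The
    candidate with the lowest SSE on the binned means wins.
    """
    model = ModelFamily.coerce(model)
    ds.require_nonempty("initial_values")
    t_bin, w_bin = _binned_means(ds)
    if len(t_bin) < 3:
        raise InsufficientDataError(
            f"initial values need >= 3 distinct ages, got {len(t_bin)}"
        )
    if w_bin.max() - w_bin.min() < 1e-12 * max(1.0, w_bin.max()):
        raise DegenerateDataError("weights are constant; no growth signal")
    w_max = float(ds.weights.max())

    best: Optional[tuple[float, ParamSet]] = None
    failures: list[str] = []
    for mult in ALPHA_MULTIPLIERS:
        try:
            theta = _start_for_alpha(model, mult * w_max, t_bin, w_bin)
        except DegenerateDataError as exc:
            failures.append(str(exc))
            continue
        sse = float(np.sum((w_bin - predict(model, theta, t_bin)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, theta)
    if best is None:
        raise DegenerateDataError(
            "no usable starting values: " + "; ".join(failures[:1])
        )
    return best[1]


def _start_for_alpha(
    model: ModelFamily, alpha0: float, t_bin: np.ndarray, w_bin: np.ndarray
) -> ParamSet:
    frac = np.clip(w_bin / alpha0, 1e-6, 1.0 - 1e-6)
    informative = frac <= 0.90
    if informative.sum() >= 3:
        t_lin, frac_lin = t_bin[informative], frac[informative]
    else:
        t_lin, frac_lin = t_bin, frac

    if model is ModelFamily.NEGATIVE_EXPONENTIAL:
        # ln(1 - W/alpha0) = -k t, regression through the origin
        y = np.log(1.0 - frac_lin)
        k0 = -float(np.dot(t_lin, y) / np.dot(t_lin, t_lin))
        _require_growth(k0)
        return ParamSet(alpha=alpha0, k=k0)

    if model in (ModelFamily.BRODY, ModelFamily.GOMPERTZ, ModelFamily.LOGISTIC):
        if model is ModelFamily.BRODY:
            y = np.log(1.0 - frac_lin)  # = ln beta - k t
        elif model is ModelFamily.GOMPERTZ:
            y = np.log(-np.log(frac_lin))  # = ln beta - k t
        else:
            y = np.log(1.0 / frac_lin - 1.0)  # = ln beta - k t
        slope, intercept = np.polyfit(t_lin, y, 1)
        k0 = -float(slope)
        _require_growth(k0)
        beta0 = float(np.exp(intercept))
        if model is ModelFamily.BRODY:
            beta0 = min(beta0, 1.0)
        return ParamSet(alpha=alpha0, beta=beta0, k=k0)

    # shape families: grid over m, profile k coarsely
    w_first = float(w_bin[np.argmin(t_bin)])
    w_first = min(w_first, 0.95 * alpha0)
    beta0 = max(w_first, 1e-3) if model is ModelFamily.MMF else alpha0 - w_first
    m_grid = np.arange(0.5, 3.0 + 1e-9, 0.25)
    k_grid = np.geomspace(1e-4, 1.0, 60)
    best = None
    for m0 in m_grid:
        theta_m = [
            ParamSet(alpha=alpha0, beta=beta0, k=float(k0), m=float(m0))
            for k0 in k_grid
        ]
        for theta in theta_m:
            sse = float(np.sum((w_bin - predict(model, theta, t_bin)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, theta)
    return best[1]


def _require_growth(k0: float) -> None:
    if not np.isfinite(k0) or k0 <= 0:
        raise DegenerateDataError(
            "linearised start gave non-positive rate k; data show no growth"
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _residuals(x_log: np.ndarray, model: ModelFamily, t: np.ndarray, w: np.ndarray):
    theta = ParamSet.from_values(model, np.exp(x_log))
    return w - _raw_predict(model, theta, t)


def _raw_predict(model: ModelFamily, theta: ParamSet, t: np.ndarray) -> np.ndarray:
    # predict() without validation: optimisation may pass through regions
    # (e.g. mmf beta > alpha) that the public API rejects.
    a, b, k, m = theta.alpha, theta.beta, theta.k, theta.m
    if model is ModelFamily.NEGATIVE_EXPONENTIAL:
        return a * (1.0 - np.exp(-k * t))
    if model is ModelFamily.BRODY:
        return a * (1.0 - b * np.exp(-k * t))
    if model is ModelFamily.GOMPERTZ:
        return a * np.exp(-b * np.exp(-k * t))
    if model is ModelFamily.LOGISTIC:
        return a / (1.0 + b * np.exp(-k * t))
    if model is ModelFamily.MMF:
        return a - (a - b) / (1.0 + (k * t) ** m)
    return a - b * np.exp(-k * t**m)


def fit(
    model: ModelFamily | str,
    ds: GrowthDataset,
    theta0: Optional[ParamSet] = None,
    max_iter: int = MAX_ITER,
    n_restarts: int = 5,
    seed: int = 20240723,
) -> FitResult:
    """Fit *model* to the pooled records of *ds* by damped least squares.

    Optimises in log-parameter space (positivity by construction) with
    Levenberg–Marquardt.  If the first solve fails to converge, or a jittered
    restart improves the SSE, the best of *n_restarts* deterministic jittered
    starts is kept.  Non-convergence is reported on the result, never raised.
    """
    model = ModelFamily.coerce(model)
    ds.require_nonempty("fit")
    # canonical record order: estimates must not depend on row order, and
    # floating-point summation is not associative
    order = ds.df.sort_values(["animal_id", "age_days"]).index.to_numpy()
    t, w = ds.ages[order], ds.weights[order]
    if len(w) < n_params(model) + 1:
        raise InsufficientDataError(
            f"{model.value} needs at least {n_params(model) + 1} records, "
            f"got {len(w)}"
        )
    if theta0 is None:
        theta0 = initial_values(model, ds)

    x0 = np.log(np.asarray(theta0.values_for(model), dtype=float))
    best = _solve(model, t, w, x0, max_iter)
    sse0 = float(np.sum(_residuals(x0, model, t, w) ** 2))

    # multi-start safety net: flat SSE surfaces (mmf/weibull) can strand LM
    if not best.success or best.cost * 2 > sse0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            x_j = x0 + rng.normal(0.0, 0.3, size=x0.size)
            cand = _solve(model, t, w, x_j, max_iter)
            if cand.cost < best.cost:
                best = cand
    log.debug(
        "fit %s/%s: sse=%.6g iters=%s status=%s",
        model.value, ds.group_label, 2 * best.cost, best.nfev, best.status,
    )

    theta_hat = ParamSet.from_values(model, np.exp(best.x))
    sse = float(np.sum((w - _raw_predict(model, theta_hat, t)) ** 2))
    sst = float(np.sum((w - w.mean()) ** 2))
    result = FitResult(
        model=model,
        group_label=ds.group_label,
        theta_hat=theta_hat,
        se=None,
        sse=sse,
        sst=sst,
        n_obs=len(w),
        converged=bool(best.success),
        n_iter=int(best.nfev),
        message=best.message,
    )
    if result.converged:
        result = replace(result, se=standard_errors(result, ds))
    return result


def _solve(model, t, w, x0, max_iter):
    return least_squares(
        _residuals,
        x0,
        args=(model, t, w),
        method="lm",
        ftol=TOL_SSE,
        xtol=TOL_STEP,
        gtol=1e-12,
        max_nfev=max_iter * (x0.size + 1),
    )


def standard_errors(
    fr: FitResult, ds: GrowthDataset
) -> Optional[dict[str, float]]:
    """Asymptotic standard errors at the fitted parameters.

    Gauss–Newton approximation: sigma̧² = SSE/(n−p) times the diagonal of
    (JᵀJ)⁻¹, where J is the Jacobian of the mean curve with respect to the
    natural (untransformed) parameters at theta_hat, evaluated by central
    finite differences.  Returns ``None`` when the degrees of freedom vanish
    (n ≤ p) or the Jacobian is rank-deficient.
    """
    names = param_names(fr.model)
    p = len(names)
    n = fr.n_obs
    if n <= p:
        return None
    t = ds.ages
    theta = np.asarray(fr.theta_hat.values_for(fr.model), dtype=float)
    J = np.empty((len(t), p))
    for j in range(p):
        h = 1e-6 * max(abs(theta[j]), 1e-8)
        hi, lo = theta.copy(), theta.copy()
        hi[j] += h
        lo[j] -= h
        J[:, j] = (
            _raw_predict(fr.model, ParamSet.from_values(fr.model, hi), t)
            - _raw_predict(fr.model, ParamSet.from_values(fr.model, lo), t)
        ) / (2 * h)
    # column-equilibrate before inverting: parameters differ by orders of
    # magnitude (alpha in hundreds of kg, k in 1/thousands of days), so a
    # raw J'J looks rank-deficient long before it actually is
    scale = np.linalg.norm(J, axis=0)
    if np.any(scale == 0) or not np.all(np.isfinite(scale)):
        return None
    Jn = J / scale
    jtj = Jn.T @ Jn
    if 1.0 / np.linalg.cond(jtj) < 1e-14:
        return None
    sigma2 = fr.sse / (n - p)
    try:
        cov = sigma2 * np.linalg.inv(jtj) / np.outer(scale, scale)
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)
    if np.any(diag < -1e-12):
        return None
    return {name: float(np.sqrt(max(d, 0.0))) for name, d in zip(names, diag)}
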