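"""Goodness-of-fit battery and model ranking.

Two information-criterion conventions are supported and must never be mixed
within one comparison:

* ``ml`` (default) — Gaussian maximum-likelihood convention.  The profile
  log-likelihood of a least-squares fit is
  ``logLik = −(n/2)(ln 2π + ln(SSE/n) + 1)`` and the criteria count the
  residual variance as a parameter: ``p_eff = p + 1``,
  ``AIC = −2 logLik + 2 p_eff``, ``BIC = −2 logLik + p_eff ln n``.  This is
  the convention R's ``AIC()``/``BIC()`` apply to an ``nls`` fit.
* ``sse`` — the textbook least-squares shortcut
  ``AIC = n ln(SSE/n) + 2p``, ``BIC = n ln(SSE/n) + p ln n`` with p the
  curve-parameter count.  It differs from ``ml`` by the constant
  ``n(ln 2π + 1) + 2``, so rankings within a group agree; the absolute
  values do not.

RMSE = sqrt(SSE/n) and adjusted R² = 1 − ((n−1)/(n−p))·(SSE/SST) are
convention-free.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import cmp_to_key
from typing import Iterable, Optional, Sequence

from .fitting import FitResult
from .models import ModelFamily, n_params

__all__ = [
    "GofReport",
    "loglik_gaussian",
    "criteria",
    "criteria_from_loglik",
    "rank_models",
    "infer_n_from_criteria",
    "CONVENTIONS",
]

CONVENTIONS = ("ml", "sse")

#: AIC differences below this are treated as ties and broken by BIC, then
#: by parameter count (parsimony).
AIC_TIE_TOL = 0.01


@dataclass(frozen=True)
class GofReport:
    """Goodness-of-fit measures for one fitted model on one group."""

    model: ModelFamily
    group_label: str
    loglik: float
    aic: float
    bic: float
    rmse: float
    r2_adj: Optional[float]
    convention: str
    p_effective: int
    n: int

    def as_row(self) -> dict:
        return {
            "model": self.model.value,
            "group": self.group_label,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "rmse": self.rmse,
            "r2_adj": self.r2_adj,
            "convention": self.convention,
            "n": self.n,
        }


def loglik_gaussian(sse: float, n: int) -> float:
    """Profile Gaussian log-likelihood of a least-squares fit.

    ``−(n/2)(ln 2π + ln(SSE/n) + 1)``: the error variance is profiled out at
    its MLE SSE/n.  A perfect fit (SSE = 0) returns +inf with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sse < 0:
        raise ValueError("sse must be non-negative")
    if sse == 0:
        warnings.warn("SSE = 0: log-likelihood is unbounded (+inf)", stacklevel=2)
        return math.inf
    return -(n / 2.0) * (math.log(2 * math.pi) + math.log(sse / n) + 1.0)


def criteria(fr: FitResult, convention: str = "ml") -> GofReport:
    """Compute the goodness-of-fit battery for a converged fit."""
    if not fr.converged:
        raise ValueError(
            f"criteria require a converged fit ({fr.model.value}/{fr.group_label})"
        )
    return _criteria(
        model=fr.model,
        group_label=fr.group_label,
        sse=fr.sse,
        sst=fr.sst,
        n=fr.n_obs,
        p=n_params(fr.model),
        convention=convention,
    )


def _criteria(model, group_label, sse, sst, n, p, convention) -> GofReport:
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    ll = loglik_gaussian(sse, n)
    rmse = math.sqrt(sse / n)
    if n > p and sst > 0:
        r2_adj = 1.0 - ((n - 1) / (n - p)) * (sse / sst)
    else:
        r2_adj = None
        warnings.warn(
            f"adjusted R^2 undefined for n={n}, p={p}", stacklevel=3
        )
    if convention == "ml":
        p_eff = p + 1  # curve parameters + residual variance
        aic = -2.0 * ll + 2.0 * p_eff
        bic = -2.0 * ll + p_eff * math.log(n)
    else:
        p_eff = p
        core = n * math.log(sse / n)
        aic = core + 2.0 * p
        bic = core + p * math.log(n)
    return GofReport(
        model=ModelFamily.coerce(model),
        group_label=group_label,
        loglik=ll,
        aic=aic,
        bic=bic,
        rmse=rmse,
        r2_adj=r2_adj,
        convention=convention,
        p_effective=p_eff,
        n=n,
    )


def criteria_from_loglik(
    loglik: float, n: int, model: ModelFamily | str, convention: str = "ml"
) -> tuple[float, float]:
    """(AIC, BIC) from a reported log-likelihood.

    Useful for reconstructing published criteria tables where only logLik is
    independent.  Only the ``ml`` convention is possible here (the ``sse``
    one needs SSE itself, use :func:`criteria`).
    """
    if convention != "ml":
        raise ValueError("criteria_from_loglik supports only the ml convention")
    p_eff = n_params(model) + 1
    return -2.0 * loglik + 2.0 * p_eff, -2.0 * loglik + p_eff * math.log(n)


def infer_n_from_criteria(
    aic: float, bic: float, model: ModelFamily | str
) -> float:
    """Back out the sample size implied by a printed (AIC, BIC) pair.

    Under the ml convention BIC − AIC = p_eff (ln n − 2), so
    n = exp((BIC − AIC)/p_eff + 2).  Consistency of the inferred n across
    models of different p is a strong internal check on a published table.
    """
    p_eff = n_params(model) + 1
    return math.exp((bic - aic) / p_eff + 2.0)


def rank_models(reports: Sequence[GofReport]) -> list[GofReport]:
    """Rank models of one group best-first.

    Primary key: ascending AIC.  AIC ties (|ΔAIC| < 0.01, i.e. equal at the
    printed precision) break by ascending BIC, then by fewer parameters,
    then by model name for determinism.  All reports must share one group
    and one convention.
    """
    reports = list(reports)
    if len(reports) < 2:
        raise ValueError("ranking requires at least two model reports")
    conventions = {r.convention for r in reports}
    if len(conventions) != 1:
        raise ValueError(f"cannot rank across conventions: {sorted(conventions)}")
    groups = {r.group_label for r in reports}
    if len(groups) != 1:
        raise ValueError(f"cannot rank across groups: {sorted(groups)}")

    def cmp(a: GofReport, b: GofReport) -> int:
        if abs(a.aic - b.aic) >= AIC_TIE_TOL:
            return -1 if a.aic < b.aic else 1
        if abs(a.bic - b.bic) >= AIC_TIE_TOL:
            return -1 if a.bic < b.bic else 1
        if a.p_effective != b.p_effective:
            return -1 if a.p_effective < b.p_effective else 1
        return -1 if a.model.value < b.model.value else (
            1 if a.model.value > b.model.value else 0
        )

    return sorted(reports, key=cmp_to_key(cmp))


def compare_fits(
    fits: Iterable[FitResult], convention: str = "ml"
) -> list[GofReport]:
    """Criteria for several converged fits of one group, ranked best-first."""
    return rank_models([criteria(fr, convention) for fr in fits])
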