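"""Goodness-of-fit battery, criteria conventions and model ranking."""

from __future__ import annotations

import math

import numpy as np
import pytest

from growthfit import GofReport, ModelFamily, criteria, loglik_gaussian, rank_models
from growthfit.fitting import fit
from growthfit.selection import (
    criteria_from_loglik,
    infer_n_from_criteria,
)

from conftest import REF_PARAMS, noise_free_dataset

# Published goodness-of-fit cells for Lori-Bakhtiari lamb fits:
# (model, group) -> (loglik, aic, bic).  These are inputs for analytic
# reconstruction checks, spanning 2-, 3- and 4-parameter families.
REF_CRITERIA = {
    ("negative_exponential", "both"): (-3144.49, 6294.98, 6309.99),
    ("negative_exponential", "male"): (-1559.08, 3124.15, 3137.09),
    ("brody", "both"): (-3097.45, 6202.90, 6222.91),
    ("gompertz", "both"): (-3099.94, 6207.89, 6227.9),
    ("gompertz", "male"): (-1496.12, 3000.24, 3017.5),
    ("gompertz", "female"): (-1418.97, 2845.93, 2863.16),
    ("logistic", "both"): (-3121.28, 6250.56, 6270.57),
    ("mmf", "both"): (-3038.53, 6087.06, 6112.08),
    ("mmf", "male"): (-1496.24, 3002.48, 3024.05),
    ("weibull", "both"): (-3094.54, 6199.08, 6224.1),
    ("weibull", "female"): (-1418.51, 2847.03, 2868.56),
}


def test_loglik_gaussian_hand_value():
    # -(n/2)(ln 2pi + ln(sse/n) + 1) with sse/n = 1
    assert loglik_gaussian(100.0, 100) == pytest.approx(-141.894, abs=5e-4)


def test_loglik_gaussian_zero_crossing():
    # choose sse so that ln 2pi + ln(sse/n) + 1 = 0
    n = 2
    sse = n * math.exp(-1) / (2 * math.pi)
    assert loglik_gaussian(sse, n) == pytest.approx(0.0, abs=1e-12)


def test_loglik_decreases_with_sse():
    assert loglik_gaussian(200.0, 100) < loglik_gaussian(100.0, 100)


def test_loglik_perfect_fit_warns_infinite():
    with pytest.warns(UserWarning):
        assert loglik_gaussian(0.0, 10) == math.inf


@pytest.mark.parametrize("key", sorted(REF_CRITERIA))
def test_ml_convention_reconstructs_published_aic(key):
    """-2 logLik + 2(p+1) reproduces every published AIC cell to the
    printed precision (the residual variance counts as a parameter)."""
    model, _ = key
    loglik, aic, bic = REF_CRITERIA[key]
    n = round(infer_n_from_criteria(aic, bic, model))
    aic_hat, bic_hat = criteria_from_loglik(loglik, n, model)
    assert aic_hat == pytest.approx(aic, abs=0.011)
    assert bic_hat == pytest.approx(bic, abs=0.05)


def test_implied_sample_size_consistent_across_models():
    """BIC - AIC = p_eff (ln n - 2): the pooled rows of the 2-, 3- and
    4-parameter families must imply one sample size within +/-3 records."""
    implied = [
        infer_n_from_criteria(aic, bic, model)
        for (model, group), (_, aic, bic) in REF_CRITERIA.items()
        if group == "both" and model in ("negative_exponential", "gompertz", "mmf")
    ]
    assert len(implied) == 3
    assert max(implied) - min(implied) <= 3.0
    assert all(1098 <= n <= 1105 for n in implied)


def test_convention_bridge_identity(small_flock):
    """ml-AIC - sse-AIC equals n(ln 2pi + 1) + 2 for 3-parameter models."""
    fr = fit("gompertz", small_flock)
    ml = criteria(fr, "ml")
    sse = criteria(fr, "sse")
    n = fr.n_obs
    assert ml.aic - sse.aic == pytest.approx(n * (math.log(2 * math.pi) + 1) + 2, rel=1e-12)
    assert ml.rmse == sse.rmse
    assert ml.r2_adj == sse.r2_adj


def test_criteria_invariants(small_flock):
    fr = fit("mmf", small_flock)
    rep = criteria(fr)
    assert rep.rmse == pytest.approx(math.sqrt(fr.sse / fr.n_obs), rel=1e-15)
    assert rep.p_effective == 5
    assert rep.aic == pytest.approx(-2 * rep.loglik + 2 * 5, rel=1e-15)
    assert rep.bic == pytest.approx(-2 * rep.loglik + 5 * math.log(fr.n_obs), rel=1e-15)
    assert rep.r2_adj is not None and rep.r2_adj <= 1.0


def test_near_perfect_fit_criteria():
    ds = noise_free_dataset("gompertz", REF_PARAMS[("gompertz", "both")], n_animals=3)
    fr = fit("gompertz", ds)
    rep = criteria(fr)
    assert rep.rmse == pytest.approx(0.0, abs=1e-7)
    assert rep.r2_adj == pytest.approx(1.0, abs=1e-9)


def test_exactly_zero_sse_criteria():
    """An exact zero SSE yields rmse 0, r2_adj 1 and an unbounded
    log-likelihood (flagged by a warning)."""
    from growthfit.fitting import FitResult
    from growthfit.models import ModelFamily
    from growthfit import ParamSet

    fr = FitResult(
        model=ModelFamily.GOMPERTZ, group_label="both",
        theta_hat=ParamSet(alpha=55.0, beta=2.5, k=0.017),
        se=None, sse=0.0, n_obs=20, converged=True, n_iter=1, sst=100.0,
    )
    with pytest.warns(UserWarning):
        rep = criteria(fr)
    assert rep.rmse == 0.0
    assert rep.r2_adj == 1.0
    assert rep.loglik == math.inf


def _report(model, aic, bic, group="male", p_eff=4):
    return GofReport(
        model=ModelFamily.coerce(model), group_label=group, loglik=-aic / 2 + p_eff,
        aic=aic, bic=bic, rmse=3.6, r2_adj=0.93, convention="ml",
        p_effective=p_eff, n=553,
    )


def test_rank_models_published_male_ordering():
    """On the published male criteria the Gompertz ranks first and the
    negative exponential last."""
    aics = {
        "negative_exponential": (3124.15, 3137.09, 3),
        "brody": (3009.64, 3026.9, 4),
        "gompertz": (3000.24, 3017.5, 4),
        "logistic": (3016.66, 3033.91, 4),
        "mmf": (3002.48, 3024.05, 5),
        "weibull": (3002.18, 3023.75, 5),
    }
    reports = [
        _report(m, aic, bic, p_eff=p) for m, (aic, bic, p) in aics.items()
    ]
    ranked = rank_models(reports)
    assert ranked[0].model.value == "gompertz"
    assert ranked[-1].model.value == "negative_exponential"


def test_rank_models_tie_breaks_on_parsimony():
    a = _report("gompertz", 3000.0, 3017.0, p_eff=4)
    b = _report("mmf", 3000.0, 3017.0, p_eff=5)
    assert rank_models([b, a])[0].model.value == "gompertz"


def test_rank_models_order_invariant():
    reports = [
        _report("gompertz", 3000.24, 3017.5),
        _report("logistic", 3016.66, 3033.91),
        _report("brody", 3009.64, 3026.9),
    ]
    fwd = [r.model for r in rank_models(reports)]
    rev = [r.model for r in rank_models(reports[::-1])]
    assert fwd == rev


def test_rank_models_rejects_mixed_or_single():
    a = _report("gompertz", 3000.0, 3017.0)
    b = GofReport(
        model=ModelFamily.MMF, group_label="male", loglik=-1.0, aic=3002.0, bic=3020.0,
        rmse=3.6, r2_adj=0.93, convention="sse", p_effective=4, n=553,
    )
    with pytest.raises(ValueError, match="convention"):
        rank_models([a, b])
    with pytest.raises(ValueError):
        rank_models([a])
    c = _report("mmf", 3002.0, 3020.0, group="female")
    with pytest.raises(ValueError, match="group"):
        rank_models([a, c])
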