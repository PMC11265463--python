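"""Growth-function values, derivatives and inflection points."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from growthfit import ModelFamily, ParamSet, agr, inflection, predict
from growthfit.models import ModelValidationError, n_params, param_names

from conftest import REF_PARAMS

ALL_MODELS = [m.value for m in ModelFamily]


def test_param_counts_match_family_definitions():
    expected = {
        "negative_exponential": 2,
        "brody": 3,
        "gompertz": 3,
        "logistic": 3,
        "mmf": 4,
        "weibull": 4,
    }
    assert {m: n_params(m) for m in ALL_MODELS} == expected


@pytest.mark.parametrize(
    "model,theta,t,expected",
    [
        # MMF starts exactly at beta; negative exponential at 0
        ("mmf", REF_PARAMS[("mmf", "male")], 0.0, 5.66),
        ("negative_exponential", REF_PARAMS[("negative_exponential", "both")], 0.0, 0.0),
        # Gompertz pooled curve at birth: alpha * exp(-beta)
        ("gompertz", REF_PARAMS[("gompertz", "both")], 0.0, 56.67 * math.exp(-2.52)),
        # Weibull at birth: alpha - beta
        ("weibull", REF_PARAMS[("weibull", "both")], 0.0, 84.9 - 81.12),
    ],
)
def test_predict_birth_weights(model, theta, t, expected):
    assert predict(model, theta, t) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("model,group", list(REF_PARAMS))
def test_predict_monotone_and_asymptotic(model, group):
    """Every reference curve rises over the study window and approaches
    its asymptote."""
    theta = REF_PARAMS[(model, group)]
    t = np.arange(0.0, 140.5, 0.5)
    w = predict(model, theta, t)
    assert np.all(np.diff(w) >= -1e-12)
    assert predict(model, theta, 1e6) == pytest.approx(theta.alpha, rel=1e-3)


@pytest.mark.parametrize(
    "model,group,t,expected,tol",
    [
        # worked examples: MMF growth rates at key ages (kg/day, 2 dp)
        ("mmf", "male", 44.0, 0.36, 0.005),
        ("mmf", "male", 140.0, 0.25, 0.005),
        ("mmf", "both", 38.0, 0.34, 0.005),
        ("negative_exponential", "both", 1e-9, 94.78 * 0.0046, 1e-5),
    ],
)
def test_agr_worked_examples(model, group, t, expected, tol):
    assert agr(model, REF_PARAMS[(model, group)], t) == pytest.approx(
        expected, abs=tol
    )


def _valid_theta(model: str, draw) -> ParamSet:
    alpha = draw(st.floats(20.0, 300.0))
    k = draw(st.floats(1e-3, 0.1))
    kv = {"alpha": alpha, "k": k}
    names = param_names(model)
    if "beta" in names:
        if model == "brody":
            kv["beta"] = draw(st.floats(0.5, 1.0))
        elif model == "mmf":
            kv["beta"] = draw(st.floats(0.5, 0.5 * alpha))
        elif model == "weibull":
            kv["beta"] = draw(st.floats(0.5, 0.95 * alpha))
        else:
            kv["beta"] = draw(st.floats(0.5, 10.0))
    if "m" in names:
        kv["m"] = draw(st.floats(1.05, 3.0))
    return ParamSet(**kv)


@settings(max_examples=200, deadline=None)
@given(data=st.data(), model=st.sampled_from(ALL_MODELS), t=st.floats(0.5, 300.0))
def test_agr_matches_finite_difference(data, model, t):
    """The analytic derivative agrees with a central finite difference of
    the mean curve (relative error below 1e-6)."""
    theta = _valid_theta(model, data.draw)
    h = 1e-4
    fd = (predict(model, theta, t + h) - predict(model, theta, t - h)) / (2 * h)
    an = agr(model, theta, t)
    # abs floor: roundoff of the difference quotient, ~eps*alpha/h
    fd_floor = 8 * np.finfo(float).eps * theta.alpha / h
    assert an == pytest.approx(fd, rel=1e-6, abs=fd_floor)


@settings(max_examples=100, deadline=None)
@given(data=st.data(), model=st.sampled_from(["gompertz", "logistic", "mmf", "weibull"]))
def test_inflection_is_argmax_of_agr(data, model):
    """Where a closed-form inflection exists, no point on a fine grid beats
    its growth rate."""
    theta = _valid_theta(model, data.draw)
    result = inflection(model, theta)
    if result is None:  # e.g. log(beta)/k <= 0
        return
    t_star, w_star = result
    grid = np.arange(0.1, 300.0001, 0.1)
    assert agr(model, theta, t_star) >= np.max(agr(model, theta, grid)) - 1e-10
    assert w_star == pytest.approx(predict(model, theta, t_star), rel=1e-12)


def test_inflection_closed_forms_reference_curves():
    t_g, w_g = inflection("gompertz", REF_PARAMS[("gompertz", "both")])
    assert t_g == pytest.approx(math.log(2.52) / 0.0168, rel=1e-12)
    assert w_g == pytest.approx(56.67 / math.e, rel=1e-12)
    assert t_g == pytest.approx(55.0, abs=0.1)

    t_m, _ = inflection("mmf", REF_PARAMS[("mmf", "male")])
    assert t_m == pytest.approx(((0.35 / 2.35) ** (1 / 1.35)) / 0.0054, rel=1e-12)
    assert t_m == pytest.approx(45.2, abs=0.05)

    t_l, w_l = inflection("logistic", REF_PARAMS[("logistic", "both")])
    assert t_l == pytest.approx(math.log(7.45) / 0.0313, rel=1e-12)
    assert w_l == pytest.approx(47.67 / 2, rel=1e-12)


@pytest.mark.parametrize("model", ["negative_exponential", "brody"])
def test_concave_models_have_no_inflection(model):
    theta = REF_PARAMS[(model, "both")]
    assert inflection(model, theta) is None


def test_shape_models_below_unit_m_have_no_inflection():
    theta = ParamSet(alpha=100.0, beta=5.0, k=0.01, m=0.9)
    assert inflection("mmf", theta) is None
    assert inflection("weibull", ParamSet(alpha=100.0, beta=95.0, k=0.01, m=1.0)) is None


def test_negative_exponential_nests_in_brody():
    """Brody with beta pinned to 1 is pointwise identical to the negative
    exponential."""
    t = np.linspace(0, 200, 101)
    ne = predict("negative_exponential", ParamSet(alpha=80.0, k=0.01), t)
    br = predict("brody", ParamSet(alpha=80.0, beta=1.0, k=0.01), t)
    np.testing.assert_allclose(ne, br, rtol=0, atol=1e-12)


def test_agr_at_zero_limits_for_shape_models():
    # m > 1: rate starts at zero
    assert agr("mmf", ParamSet(alpha=100, beta=5, k=0.01, m=1.5), 0.0) == 0.0
    # m == 1: finite limits (alpha-beta)k and beta*k
    assert agr("mmf", ParamSet(alpha=100, beta=5, k=0.01, m=1.0), 0.0) == pytest.approx(
        0.95, rel=1e-12
    )
    assert agr(
        "weibull", ParamSet(alpha=100, beta=95, k=0.01, m=1.0), 0.0
    ) == pytest.approx(0.95, rel=1e-12)
    # m < 1: divergent, reported as +inf with a warning
    with pytest.warns(UserWarning):
        assert agr("mmf", ParamSet(alpha=100, beta=5, k=0.01, m=0.8), 0.0) == math.inf


def test_invalid_inputs_rejected():
    theta = REF_PARAMS[("gompertz", "both")]
    with pytest.raises(ValueError):
        predict("gompertz", theta, -1.0)
    with pytest.raises(ModelValidationError):
        predict("gompertz", ParamSet(alpha=-5.0, beta=2.0, k=0.01), 10.0)
    with pytest.raises(ModelValidationError):
        predict("mmf", ParamSet(alpha=50.0, beta=60.0, k=0.01, m=1.2), 10.0)
    with pytest.raises(ModelValidationError):
        predict("richards", theta, 1.0)


def test_brody_beta_above_one_warns_but_evaluates():
    with pytest.warns(UserWarning, match="beta"):
        w = predict("brody", ParamSet(alpha=100.0, beta=1.05, k=0.01), 50.0)
    assert np.isfinite(w)
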