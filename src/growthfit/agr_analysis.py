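"""Absolute growth rate (AGR) curves, peaks and point evaluations.

The AGR is the first derivative of the fitted mean curve, dW/dt in kg/day.
For sigmoid families the AGR is unimodal and its maximum coincides with the
curve's inflection point; for the negative exponential and Brody curves (and
the shape families with m ≤ 1) the AGR is strictly decreasing, so no peak is
reported — the rate at t → 0⁺ is exposed separately as the *initial rate*,
never dressed up as a peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .models import ModelFamily, ParamSet, agr, inflection, SHAPE_MODELS

__all__ = ["AgrSummary", "agr_summary", "agr_curve_table", "numeric_peak"]

DEFAULT_HORIZON = 140.0  # days: the study window, birth to 140 d


@dataclass
class AgrSummary:
    """AGR curve summary for one parameter set."""

    model: ModelFamily
    group_label: str
    peak_time: Optional[float]  # days; None when AGR is monotone decreasing
    peak_value: Optional[float]  # kg/day
    initial_rate: Optional[float]  # kg/day at t -> 0+, for monotone curves
    agr_at: dict[float, float] = field(default_factory=dict)
    grid: pd.DataFrame = field(default_factory=pd.DataFrame)  # columns t, agr

    @property
    def has_peak(self) -> bool:
        return self.peak_time is not None


def numeric_peak(
    model: ModelFamily | str,
    theta: ParamSet,
    horizon: float = DEFAULT_HORIZON,
) -> tuple[float, float]:
    """Numeric argmax of the AGR over (0, horizon].

    Coarse 1-day grid followed by bounded golden-section refinement.  Used
    as a fallback when no closed form applies, and handy as an independent
    cross-check of the closed forms.
    """
    model = ModelFamily.coerce(model)
    t_grid = np.arange(1.0, horizon + 1e-9, 1.0)
    if t_grid.size == 0:
        t_grid = np.array([horizon])
    vals = agr(model, theta, t_grid)
    i = int(np.argmax(vals))
    lo = t_grid[max(i - 1, 0)]
    hi = min(t_grid[min(i + 1, t_grid.size - 1)], horizon)
    if hi - lo < 1e-12:
        return float(t_grid[i]), float(vals[i])
    res = minimize_scalar(
        lambda t: -agr(model, theta, t),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x), float(-res.fun)


def agr_summary(
    model: ModelFamily | str,
    theta: ParamSet,
    group_label: str = "both",
    horizon: float = DEFAULT_HORIZON,
    at_ages: Sequence[float] = (),
    step: float = 1.0,
) -> AgrSummary:
    """Summarise the AGR curve of one parameter set.

    The peak is taken from the closed-form inflection when one exists and
    falls inside (0, horizon]; otherwise a grid-plus-golden-section search
    refines it.  Monotone-decreasing curves report no peak, only the
    initial rate.  ``agr_at`` evaluates the AGR at requested ages (days).
    """
    model = ModelFamily.coerce(model)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if step <= 0:
        raise ValueError("step must be positive")

    monotone = model in (
        ModelFamily.NEGATIVE_EXPONENTIAL,
        ModelFamily.BRODY,
    ) or (model in SHAPE_MODELS and theta.m is not None and theta.m <= 1.0)

    peak_time = peak_value = initial_rate = None
    if monotone:
        initial_rate = float(agr(model, theta, 0.0))
    else:
        closed = inflection(model, theta)
        if closed is not None and 0.0 < closed[0] <= horizon:
            peak_time = float(closed[0])
            peak_value = float(agr(model, theta, peak_time))
        else:
            t_num, v_num = numeric_peak(model, theta, horizon)
            # a maximum sitting on the horizon is a window edge, not a peak
            if t_num < horizon - 1e-6:
                peak_time, peak_value = t_num, v_num
            else:
                initial_rate = float(agr(model, theta, 0.0))

    t_grid = np.arange(0.0, horizon + 1e-9, step)
    if t_grid.size == 0:
        t_grid = np.array([0.0])
    grid = pd.DataFrame({"t": t_grid, "agr": np.asarray(agr(model, theta, t_grid))})
    agr_at = {float(age): float(agr(model, theta, float(age))) for age in at_ages}
    return AgrSummary(
        model=model,
        group_label=group_label,
        peak_time=peak_time,
        peak_value=peak_value,
        initial_rate=initial_rate,
        agr_at=agr_at,
        grid=grid,
    )


def agr_curve_table(
    summaries: Sequence[AgrSummary], step: Optional[float] = None
) -> pd.DataFrame:
    """Long-format (group, model, t, agr) table for external plotting.

    With ``step`` given, each summary's grid is resampled to multiples of
    ``step`` inside its own horizon; otherwise the stored grids are used.
    """
    frames = []
    for s in summaries:
        g = s.grid
        if step is not None:
            if step <= 0:
                raise ValueError("step must be positive")
            horizon = float(g["t"].max()) if len(g) else 0.0
            t_new = np.arange(0.0, horizon + 1e-9, step)
            if t_new.size == 0:
                t_new = np.array([0.0])
            g = pd.DataFrame({"t": t_new, "agr": np.interp(t_new, g["t"], g["agr"])})
        g = g.copy()
        g.insert(0, "model", s.model.value)
        g.insert(0, "group", s.group_label)
        frames.append(g)
    return pd.concat(frames, ignore_index=True)
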