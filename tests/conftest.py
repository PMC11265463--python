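"""Shared fixtures: published reference parameter sets and synthetic data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from growthfit import GrowthDataset, ParamSet, SimConfig, predict, simulate_flock

# Published parameter means for Lori-Bakhtiari lambs, by (model, group).
# These drive worked examples and parameter-recovery simulations.
REF_PARAMS: dict[tuple[str, str], ParamSet] = {
    ("negative_exponential", "both"): ParamSet(alpha=94.78, k=0.0046),
    ("negative_exponential", "male"): ParamSet(alpha=91.92, k=0.0055),
    ("negative_exponential", "female"): ParamSet(alpha=59.63, k=0.0085),
    ("brody", "both"): ParamSet(alpha=218.03, beta=0.99, k=0.0016),
    ("brody", "male"): ParamSet(alpha=268.92, beta=0.98, k=0.0014),
    ("brody", "female"): ParamSet(alpha=99.81, beta=0.96, k=0.0037),
    ("gompertz", "both"): ParamSet(alpha=56.67, beta=2.52, k=0.0168),
    ("gompertz", "male"): ParamSet(alpha=64.47, beta=2.39, k=0.0156),
    ("gompertz", "female"): ParamSet(alpha=49.28, beta=2.21, k=0.0181),
    ("logistic", "both"): ParamSet(alpha=47.67, beta=7.45, k=0.0313),
    ("logistic", "male"): ParamSet(alpha=53.71, beta=6.74, k=0.0294),
    ("logistic", "female"): ParamSet(alpha=42.86, beta=5.81, k=0.032),
    ("mmf", "both"): ParamSet(alpha=124.04, beta=5.19, k=0.0043, m=1.24),
    ("mmf", "male"): ParamSet(alpha=113.51, beta=5.66, k=0.0054, m=1.35),
    ("mmf", "female"): ParamSet(alpha=78.82, beta=5.08, k=0.0048, m=1.33),
    ("weibull", "both"): ParamSet(alpha=84.9, beta=81.12, k=0.0022, m=1.18),
    ("weibull", "male"): ParamSet(alpha=77.77, beta=72.02, k=0.0017, m=1.28),
    ("weibull", "female"): ParamSet(alpha=56.86, beta=51.71, k=0.0027, m=1.24),
}

STUDY_AGES = tuple(range(0, 141, 10))


def noise_free_dataset(
    model: str,
    theta: ParamSet,
    n_animals: int = 20,
    ages=STUDY_AGES,
    sex: str = "male",
) -> GrowthDataset:
    """Records lying exactly on the mean curve (zero-residual fixed point)."""
    rows = []
    mean = np.asarray(predict(model, theta, np.asarray(ages, float)))
    for i in range(n_animals):
        for age, w in zip(ages, mean):
            if w <= 0:  # e.g. the negative exponential starts at exactly 0
                continue
            rows.append((f"{sex[0].upper()}{i + 1:03d}", sex, int(age), float(w)))
    df = pd.DataFrame(rows, columns=["animal_id", "sex", "age_days", "weight_kg"])
    label = sex if sex in ("male", "female") else "both"
    return GrowthDataset(df, group_label=label)


@pytest.fixture(scope="session")
def default_flock() -> GrowthDataset:
    """One study-design flock with the generator defaults (85 lambs,
    ages 0..140 by 10, Gompertz truth, residual SD 3.4, animal CV 0.10)."""
    return simulate_flock(SimConfig(seed=20240723))


@pytest.fixture(scope="session")
def small_flock() -> GrowthDataset:
    """A lighter flock for fast end-to-end tests."""
    return simulate_flock(SimConfig(n_male=8, n_female=9, seed=11))
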