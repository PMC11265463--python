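"""Synthetic flock generator.

Emulates the study design behind the package: 85 lambs (41 male, 44 female)
weighed every 10 days from birth to 140 days (15 scheduled measurements per
animal).  Each animal draws an individual asymptote
``alpha_i = alpha (1 + cv z_i)`` with z_i standard normal, giving realistic
between-animal spread; weights are the model mean curve plus homoscedastic
Gaussian noise, truncated below at 0.25 kg so no record is non-positive.
Records can be dropped completely at random to emulate missed weighings.

Defaults are the study conditions: sex-specific Gompertz mean curves
(male alpha=64.47, beta=2.39, k=0.0156; female alpha=49.28, beta=2.21,
k=0.0181), residual SD 3.4 kg (the middle of the fitted RMSE range),
animal CV 0.10 and no missingness.  Everything is reproducible from the
seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import GrowthDataset
from .models import ModelFamily, ParamSet, param_names, predict

__all__ = [
    "SimConfig",
    "DEFAULT_THETA_MALE",
    "DEFAULT_THETA_FEMALE",
    "simulate_flock",
    "study_emulation_summary",
]

DEFAULT_THETA_MALE = ParamSet(alpha=64.47, beta=2.39, k=0.0156)
DEFAULT_THETA_FEMALE = ParamSet(alpha=49.28, beta=2.21, k=0.0181)

WEIGHT_FLOOR_KG = 0.25


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated flock.

    ``animal_cv`` scales per-animal variation of the asymptote only;
    ``vary_all_params`` extends the same relative variation to every curve
    parameter.  ``heteroscedastic`` makes the residual SD proportional to
    the mean weight (scaled so the average SD equals ``residual_sd``);
    the default is the constant-variance error the least-squares criteria
    assume.  ``missing_rate`` drops records completely at random; 0.135
    emulates a flock where roughly one record in seven was missed.
    """

    n_male: int = 41
    n_female: int = 44
    ages: tuple[int, ...] = tuple(range(0, 141, 10))
    true_model: ModelFamily = ModelFamily.GOMPERTZ
    theta_male: ParamSet = DEFAULT_THETA_MALE
    theta_female: ParamSet = DEFAULT_THETA_FEMALE
    animal_cv: float = 0.10
    residual_sd: float = 3.4
    missing_rate: float = 0.0
    heteroscedastic: bool = False
    vary_all_params: bool = False
    seed: int = 20240723

    def validate(self) -> None:
        if self.n_male < 0 or self.n_female < 0 or self.n_male + self.n_female == 0:
            raise ValueError("need at least one animal")
        ages = np.asarray(self.ages)
        if ages.size == 0 or ages[0] != 0 or np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing and start at 0")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.animal_cv < 0:
            raise ValueError("animal_cv must be non-negative")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _individual_theta(
    cfg: SimConfig, base: ParamSet, rng: np.random.Generator
) -> ParamSet:
    names = param_names(cfg.true_model)
    values = {}
    for name in names:
        v = getattr(base, name)
        if cfg.vary_all_params or name == "alpha":
            v = v * max(1.0 + cfg.animal_cv * rng.standard_normal(), 0.05)
        values[name] = v
    return ParamSet(**values)


def simulate_flock(cfg: SimConfig) -> GrowthDataset:
    """Generate one flock under *cfg*; byte-identical for identical configs."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ages = np.asarray(cfg.ages, dtype=float)
    rows = []
    groups = (("male", cfg.n_male, cfg.theta_male),
              ("female", cfg.n_female, cfg.theta_female))
    for sex, n_animals, base in groups:
        for i in range(n_animals):
            animal_id = f"{sex[0].upper()}{i + 1:03d}"
            theta_i = _individual_theta(cfg, base, rng)
            mean = np.asarray(predict(cfg.true_model, theta_i, ages))
            if cfg.heteroscedastic:
                sd = cfg.residual_sd * mean / max(mean.mean(), 1e-9)
            else:
                sd = np.full_like(mean, cfg.residual_sd)
            w = mean + sd * rng.standard_normal(ages.size)
            w = np.maximum(w, WEIGHT_FLOOR_KG)
            keep = (
                rng.random(ages.size) >= cfg.missing_rate
                if cfg.missing_rate > 0
                else np.ones(ages.size, dtype=bool)
            )
            for age, weight, k in zip(cfg.ages, w, keep):
                if k:
                    rows.append((animal_id, sex, int(age), float(weight)))
    df = pd.DataFrame(rows, columns=["animal_id", "sex", "age_days", "weight_kg"])
    if df.empty:
        raise ValueError(
            "simulation produced no records (missing_rate too aggressive?)"
        )
    return GrowthDataset(df, group_label="both")


def study_emulation_summary(
    ds: GrowthDataset, cfg: Optional[SimConfig] = None
) -> dict:
    """Quality-control summary of a (simulated or real) flock.

    Returns per-sex mean weight by age, per-sex record and animal counts,
    and — when the generating :class:`SimConfig` is supplied — the residual
    SD of the records around the sex-specific generating mean curves.
    """
    ds.require_nonempty("study_emulation_summary")
    mean_by_age = (
        ds.df.pivot_table(
            index="age_days", columns="sex", values="weight_kg", aggfunc="mean"
        )
        .reindex(columns=["male", "female"])
    )
    counts = {
        sex: {
            "n_records": int((ds.df["sex"] == sex).sum()),
            "n_animals": int(ds.df.loc[ds.df["sex"] == sex, "animal_id"].nunique()),
        }
        for sex in ("male", "female")
    }
    out = {
        "mean_weight_by_age": mean_by_age,
        "counts": counts,
        "n_records": ds.n_records,
    }
    if cfg is not None:
        resid = []
        for sex, base in (("male", cfg.theta_male), ("female", cfg.theta_female)):
            sub = ds.df[ds.df["sex"] == sex]
            if len(sub):
                mean = np.asarray(
                    predict(cfg.true_model, base, sub["age_days"].to_numpy(float))
                )
                resid.append(sub["weight_kg"].to_numpy(float) - mean)
        resid = np.concatenate(resid) if resid else np.array([])
        out["residual_sd"] = float(resid.std(ddof=0)) if resid.size else 0.0
    return out
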