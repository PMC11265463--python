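"""Reading, validating and writing long-format lamb weight records.

The canonical on-disk format is a UTF-8 CSV with header
``animal_id,sex,age_days,weight_kg`` — one row per measurement.  Ages are
integer days since birth (the study design is day-indexed, so no date
arithmetic), weights are kilograms.  Sex is coded ``male``/``female``;
``M``/``F`` and any capitalisation are accepted on input and normalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "GrowthDataset",
    "SchemaError",
    "DataValidationError",
    "EmptyDatasetError",
    "read_weight_records",
    "write_weight_records",
    "split_by_sex",
    "write_report",
]

REQUIRED_COLUMNS = ("animal_id", "sex", "age_days", "weight_kg")

_SEX_CODES = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
}


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class DataValidationError(ValueError):
    """A row violates the record invariants (bad sex code, duplicate,
    non-positive weight, negative age...)."""


class EmptyDatasetError(ValueError):
    """An operation received, or produced, a dataset with no records."""


def normalize_sex(value: str) -> str:
    key = str(value).strip().lower()
    if key not in _SEX_CODES:
        raise DataValidationError(
            f"sex code {value!r} not recognised (accepted: M, F, male, female)"
        )
    return _SEX_CODES[key]


@dataclass
class GrowthDataset:
    """Long-format weight records for one analysis group.

    Wraps a :class:`pandas.DataFrame` with the four canonical columns.
    ``group_label`` is ``both``, ``male`` or ``female``; a sex-restricted
    dataset may only contain records of that sex.  Duplicate
    ``(animal_id, age_days)`` pairs are an error — repeated weighings on the
    same day indicate a data problem and are never silently averaged.
    """

    df: pd.DataFrame
    group_label: str = "both"
    n_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if self.group_label not in ("both", "male", "female"):
            raise DataValidationError(
                f"group_label must be both/male/female, got {self.group_label!r}"
            )
        df = self.df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["animal_id"] = df["animal_id"].astype(str)
        df["sex"] = df["sex"].map(normalize_sex)
        df["age_days"] = _to_int_ages(df["age_days"])
        df["weight_kg"] = pd.to_numeric(df["weight_kg"], errors="raise").astype(float)
        if (df["age_days"] < 0).any():
            bad = df.loc[df["age_days"] < 0].index[0]
            raise DataValidationError(f"negative age_days at row {bad}")
        if (df["weight_kg"] <= 0).any():
            bad = df.loc[df["weight_kg"] <= 0].index[0]
            raise DataValidationError(f"non-positive weight_kg at row {bad}")
        dup = df.duplicated(subset=["animal_id", "age_days"])
        if dup.any():
            pair = df.loc[dup, ["animal_id", "age_days"]].iloc[0]
            raise DataValidationError(
                f"duplicate measurement for animal {pair.animal_id!r} at "
                f"age {pair.age_days}; duplicates are not averaged"
            )
        if self.group_label != "both" and (df["sex"] != self.group_label).any():
            raise DataValidationError(
                f"dataset labelled {self.group_label!r} contains records of "
                "the other sex"
            )
        self.df = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_animals(self) -> int:
        return self.df["animal_id"].nunique()

    @property
    def ages(self) -> np.ndarray:
        """Age vector (days), one entry per record."""
        return self.df["age_days"].to_numpy(dtype=float)

    @property
    def weights(self) -> np.ndarray:
        """Weight vector (kg), one entry per record."""
        return self.df["weight_kg"].to_numpy(dtype=float)

    def require_nonempty(self, what: str = "operation") -> None:
        if len(self.df) == 0:
            raise EmptyDatasetError(f"{what} requires a non-empty dataset")


def _to_int_ages(col: pd.Series) -> pd.Series:
    vals = pd.to_numeric(col, errors="raise")
    rounded = vals.round()
    if not np.allclose(vals, rounded, atol=1e-9):
        raise DataValidationError("age_days must be whole days")
    return rounded.astype(int)


def read_weight_records(
    path: "str | Path",
    column_map: Optional[dict[str, str]] = None,
    delimiter: str = ",",
) -> GrowthDataset:
    """Read a long-format weight CSV into a :class:`GrowthDataset`.

    Rows with a missing (blank/NA) weight are dropped; the count is exposed
    as ``dataset.n_dropped``.  ``column_map`` renames non-standard headers,
    e.g. ``{"id": "animal_id"}``.

    Raises :class:`SchemaError` for a missing column, ``ValueError`` with the
    offending row index for non-numeric fields, and
    :class:`EmptyDatasetError` if nothing remains.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError:
        raise EmptyDatasetError(f"{path} contains no data") from None
    if column_map:
        raw = raw.rename(columns=column_map)
    raw.columns = [str(c).strip() for c in raw.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )

    weight = pd.to_numeric(raw["weight_kg"], errors="coerce")
    blank = raw["weight_kg"].isna() | raw["weight_kg"].astype(str).str.strip().eq("")
    bad = weight.isna() & ~blank
    if bad.any():
        # +2: header line plus 1-based indexing
        line = int(bad.idxmax()) + 2
        raise DataValidationError(
            f"{path}: non-numeric weight_kg at line {line}"
        )
    kept = raw.loc[weight.notna()].copy()
    kept["weight_kg"] = weight.loc[weight.notna()]
    n_dropped = int(weight.isna().sum())
    if kept.empty:
        raise EmptyDatasetError(f"{path}: no usable weight records")

    try:
        pd.to_numeric(kept["age_days"], errors="raise")
    except (ValueError, TypeError):
        numeric = pd.to_numeric(kept["age_days"], errors="coerce")
        line = int(numeric.isna().idxmax()) + 2
        raise DataValidationError(
            f"{path}: non-numeric age_days at line {line}"
        ) from None

    return GrowthDataset(kept, group_label="both", n_dropped=n_dropped)


def write_weight_records(ds: GrowthDataset, path: "str | Path") -> None:
    """Write a dataset back to the canonical CSV format."""
    ds.df.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def split_by_sex(ds: GrowthDataset) -> tuple[GrowthDataset, GrowthDataset]:
    """Split a pooled dataset into (male, female) datasets.

    Record counts of the two outputs always sum to the input count.  Either
    output may be empty (e.g. a single-sex input); downstream fitting flags
    that via its own non-empty precondition.
    """
    ds.require_nonempty("split_by_sex")
    male = ds.df[ds.df["sex"] == "male"]
    female = ds.df[ds.df["sex"] == "female"]
    return (
        GrowthDataset(male, group_label="male"),
        GrowthDataset(female, group_label="female"),
    )


def _fmt_sig(x: float, sig: int = 4) -> str:
    return f"{x:.{sig}g}" if x is not None and np.isfinite(x) else ""


def write_report(
    results: Iterable[tuple],
    path: "str | Path",
    fmt: str = "csv",
) -> pd.DataFrame:
    """Write a combined parameter + goodness-of-fit report.

    *results* is an iterable of ``(FitResult, GofReport)`` pairs; one output
    row per (model, group).  Parameters and their standard errors are printed
    to 4 significant figures, criteria to 2 decimals.  ``fmt`` is ``csv`` or
    ``text`` (aligned columns).  Returns the report as a DataFrame.
    """
    results = list(results)
    if not results:
        raise EmptyDatasetError("write_report requires at least one result")
    rows = []
    for fit_result, gof in results:
        row: dict[str, object] = {
            "model": fit_result.model.value,
            "group": fit_result.group_label,
        }
        params = fit_result.theta_hat.as_dict(fit_result.model)
        for name in ("alpha", "beta", "k", "m"):
            row[name] = _fmt_sig(params.get(name))
            se = (fit_result.se or {}).get(name)
            row[f"se_{name}"] = _fmt_sig(se) if se is not None else ""
        row.update(
            n=fit_result.n_obs,
            loglik=f"{gof.loglik:.2f}",
            aic=f"{gof.aic:.2f}",
            bic=f"{gof.bic:.2f}",
            rmse=f"{gof.rmse:.2f}",
            r2_adj=f"{gof.r2_adj:.2f}" if gof.r2_adj is not None else "",
            converged=fit_result.converged,
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    path = Path(path)
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt == "text":
        path.write_text(table.to_string(index=False) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r} (use csv or text)")
    return table
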