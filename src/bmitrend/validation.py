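"""Forecast scoring against held-out survey years.

Predicted five-category prevalences are compared with prevalences observed
in reserved survey years, cell by cell over sex and eight adult age groups,
pooling all cells with equal weight into one mean absolute error and one
RMSE per model family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection import DEFAULT_SCHEME, BMICategoryScheme, project

#: lower edges of the standard adult age groups (last is open-ended)
DEFAULT_AGE_GROUP_EDGES = (18, 25, 35, 45, 55, 65, 75, 85)


def age_group_labels(edges=DEFAULT_AGE_GROUP_EDGES) -> list[str]:
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f"{edges[-1]}+")
    return labels


def assign_age_group(ages, edges=DEFAULT_AGE_GROUP_EDGES) -> np.ndarray:
    ages = np.asarray(ages)
    if np.any(ages < edges[0]):
        raise ValueError(f"ages below the first group edge {edges[0]}")
    idx = np.searchsorted(edges, ages, side="right") - 1
    return np.asarray(age_group_labels(edges), dtype=object)[idx]


def categorize_bmi(bmi, scheme: BMICategoryScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Category labels; interior intervals are left-closed ([25, 30) etc.)."""
    idx = np.searchsorted(scheme.cuts, np.asarray(bmi, dtype=float), side="right")
    return np.asarray(scheme.names, dtype=object)[idx]


def observed_category_prevalence(
    records: pd.DataFrame,
    scheme: BMICategoryScheme = DEFAULT_SCHEME,
    edges=DEFAULT_AGE_GROUP_EDGES,
) -> pd.DataFrame:
    """Observed category shares per (year, sex, age_group); shares sum to 1.

    Cells with no records are simply absent (omitted with a warning), never
    zero-filled.
    """
    if len(records) == 0:
        raise ValueError("no records")
    df = records.copy()
    df["age_group"] = assign_age_group(df["age"], edges)
    df["category"] = categorize_bmi(df["bmi"], scheme)
    counts = (
        df.groupby(["year", "sex", "age_group", "category"], observed=True)
        .size()
        .unstack("category", fill_value=0)
    )
    for name in scheme.names:
        if name not in counts.columns:
            counts[name] = 0
    counts = counts[list(scheme.names)]
    total = counts.sum(axis=1)
    shares = counts.div(total, axis=0)
    shares["n"] = total
    out = shares.reset_index()
    n_possible = df["year"].nunique() * 2 * len(age_group_labels(edges))
    if len(out) < n_possible:
        warnings.warn(
            f"{n_possible - len(out)} empty (year, sex, age_group) cells omitted",
            stacklevel=2,
        )
    return out


def predicted_category_prevalence(
    mu_model,
    sigma_model,
    records: pd.DataFrame,
    scheme: BMICategoryScheme = DEFAULT_SCHEME,
    edges=DEFAULT_AGE_GROUP_EDGES,
) -> pd.DataFrame:
    """Model-predicted shares on the observed cells.

    Single-age model predictions are averaged within each age group using
    the observed record counts per age as weights, so predicted and
    observed tables describe the same population mix.
    """
    wts = (
        records.groupby(["year", "sex", "age"]).size().rename("count").reset_index()
    )
    years = sorted(records["year"].unique())
    ages = sorted(records["age"].unique())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cells = project(mu_model, sigma_model, years, ages, population=None, scheme=scheme)
    cells = cells.merge(wts, on=["year", "sex", "age"], how="inner")
    cells["age_group"] = assign_age_group(cells["age"], edges)
    cats = list(scheme.names)

    def _agg(g):
        w = g["count"].to_numpy(dtype=float)
        w = w / w.sum()
        return pd.Series({c: float(np.dot(w, g[c])) for c in cats})

    out = (
        cells.groupby(["year", "sex", "age_group"])
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return out


def _long(table: pd.DataFrame, value_name: str, cats) -> pd.DataFrame:
    return table.melt(
        id_vars=["year", "sex", "age_group"],
        value_vars=list(cats),
        var_name="category",
        value_name=value_name,
    )


def mae(predicted: pd.DataFrame, observed: pd.DataFrame, scheme=DEFAULT_SCHEME) -> float:
    """Mean absolute prevalence error pooled over all aligned cells (proportion
    scale; multiply by 100 for percentage points)."""
    joined = _join(predicted, observed, scheme)
    return float(np.abs(joined["predicted"] - joined["observed"]).mean())


def _join(predicted, observed, scheme):
    p = _long(predicted, "predicted", scheme.names)
    o = _long(observed, "observed", scheme.names)
    joined = p.merge(o, on=["year", "sex", "age_group", "category"], how="outer")
    bad = joined["predicted"].isna() | joined["observed"].isna()
    if bad.any():
        keys = joined.loc[bad, ["year", "sex", "age_group"]].drop_duplicates()
        raise ValueError(
            f"predicted and observed tables misaligned on cells: {keys.to_dict('records')}"
        )
    return joined


@dataclass
class ValidationReport:
    cells: pd.DataFrame  # year, sex, age_group, category, predicted, observed, residual
    mae: float
    rmse: float
    n_cells: int

    @property
    def mae_pct(self) -> float:
        return 100 * self.mae

    def summary(self) -> dict:
        return {
            "mae": self.mae,
            "mae_pct": self.mae_pct,
            "rmse": self.rmse,
            "n_cells": self.n_cells,
        }


def validate(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    scheme: BMICategoryScheme = DEFAULT_SCHEME,
) -> ValidationReport:
    """Join predicted and observed cell tables and score them."""
    joined = _join(predicted, observed, scheme)
    if len(joined) == 0:
        raise ValueError("no overlapping cells to validate on")
    joined["residual"] = joined["predicted"] - joined["observed"]
    err = joined["residual"].to_numpy()
    return ValidationReport(
        cells=joined,
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt(np.mean(err**2))),
        n_cells=len(joined),
    )


def validate_models(
    mu_model,
    sigma_model,
    heldout_records: pd.DataFrame,
    scheme: BMICategoryScheme = DEFAULT_SCHEME,
    edges=DEFAULT_AGE_GROUP_EDGES,
) -> ValidationReport:
    """End-to-end scoring of a fitted model pair on held-out survey records."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        observed = observed_category_prevalence(heldout_records, scheme, edges)
    predicted = predicted_category_prevalence(
        mu_model, sigma_model, heldout_records, scheme, edges
    )
    observed = observed.drop(columns=["n"])
    return validate(predicted, observed, scheme)
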