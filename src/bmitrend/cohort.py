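"""Survey filtering, birth-cohort construction and per-cell distribution fits.

The regression stages do not see individual BMI records: per survey year,
records are grouped into ten-year birth cohorts (sex-specific cells), and
each (sex, cohort, year) cell is summarised by its mean age and the
parameters of a lognormal fitted to its BMI values. Those cell-level
mu-hat / sigma-hat observations are what the trend models are fitted to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .terms import center_year


class EmptyDatasetError(ValueError):
    """A filter or grouping left no usable data."""


def filter_records(
    records: pd.DataFrame,
    bmi_min: float = 10.0,
    bmi_max: float = 65.0,
    age_min: int = 18,
) -> tuple[pd.DataFrame, float]:
    """Keep adult records with plausible BMI; bounds are inclusive.

    Returns the kept records and the fraction removed. Implausibly low BMI
    values occur in some survey years, hence the hard 10-65 kg/m2 window.
    """
    if len(records) == 0:
        raise EmptyDatasetError("no records to filter")
    keep = (
        (records["age"] >= age_min)
        & (records["bmi"] >= bmi_min)
        & (records["bmi"] <= bmi_max)
    )
    kept = records.loc[keep].reset_index(drop=True)
    if len(kept) == 0:
        raise EmptyDatasetError("all records removed by BMI/age filters")
    return kept, float((~keep).mean())


def assign_cohorts(records: pd.DataFrame, width: int = 10) -> pd.DataFrame:
    """Annotate records with a birth-cohort label: birth year floored to `width`."""
    out = records.copy()
    birth_year = out["year"] - out["age"]
    out["cohort_label"] = (birth_year // width) * width
    return out


def fit_lognormal(values) -> tuple[float, float]:
    """Closed-form lognormal MLE: (mean, population SD) of log(values)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to fit a lognormal")
    if np.any(v <= 0):
        raise ValueError("lognormal fit requires strictly positive values")
    logs = np.log(v)
    return float(logs.mean()), float(logs.std(ddof=0))


@dataclass
class DistributionComparison:
    """KS-based comparison of lognormal, gamma and Weibull fits."""

    fits: dict  # family -> {"params": tuple, "ks": float} or {"error": str}
    winner: str

    @property
    def ks_statistics(self) -> dict:
        return {k: v["ks"] for k, v in self.fits.items() if "ks" in v}


_FAMILIES = {
    "lognormal": stats.lognorm,
    "gamma": stats.gamma,
    "weibull": stats.weibull_min,
}


def compare_distributions(values) -> DistributionComparison:
    """Fit the three candidate BMI distributions by ML and rank by KS statistic.

    All three are two-parameter fits (location fixed at 0, the convention
    for strictly positive measurements). The winner has the smallest
    Kolmogorov-Smirnov statistic against its own fitted distribution.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 30:
        raise ValueError("need at least 30 values for a distribution comparison")
    if np.any(v <= 0):
        raise ValueError("distribution comparison requires positive values")
    fits: dict = {}
    for name, dist in _FAMILIES.items():
        try:
            params = dist.fit(v, floc=0)
            ks = stats.kstest(v, dist.cdf, args=params).statistic
            if not np.isfinite(ks):
                raise ValueError("non-finite KS statistic")
            fits[name] = {"params": params, "ks": float(ks)}
        except Exception as exc:  # noqa: BLE001 - any fit failure excludes the family
            warnings.warn(f"{name} fit failed and is excluded: {exc}", stacklevel=2)
            fits[name] = {"error": str(exc)}
    scored = {k: v["ks"] for k, v in fits.items() if "ks" in v}
    if not scored:
        raise ValueError("all candidate distribution fits failed")
    return DistributionComparison(fits=fits, winner=min(scored, key=scored.get))


def cullen_frey(values) -> tuple[float, float]:
    """Squared sample skewness and (non-excess) kurtosis, the diagnostic pair
    used to screen candidate distributions (normal maps to (0, 3))."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values")
    if np.isclose(v.var(), 0.0):
        raise ValueError("moments undefined for zero-variance sample")
    skew = stats.skew(v, bias=True)
    kurt = stats.kurtosis(v, fisher=False, bias=True)
    return float(skew**2), float(kurt)


def build_cohort_dataset(records: pd.DataFrame, min_cell_n: int = 50) -> pd.DataFrame:
    """Summarise filtered, cohort-annotated records into cell observations.

    One row per (sex, cohort_label, survey year) with at least ``min_cell_n``
    records: mean age, cell size, and the lognormal (mu_hat, sigma_hat) of
    the cell's BMI values. Cells are sex-specific because sex enters the
    trend models as a covariate of cell-level parameters.
    """
    if "cohort_label" not in records.columns:
        raise ValueError("records must be cohort-annotated (run assign_cohorts)")
    rows = []
    for (sex, cohort, year), cell in records.groupby(["sex", "cohort_label", "year"]):
        if len(cell) < min_cell_n:
            continue
        mu_hat, sigma_hat = fit_lognormal(cell["bmi"].to_numpy())
        rows.append(
            {
                "cohort_label": int(cohort),
                "year": int(year),
                "year_c": float(center_year(year)),
                "sex": int(sex),
                "mean_age": float(cell["age"].mean()),
                "n": int(len(cell)),
                "mu_hat": mu_hat,
                "sigma_hat": sigma_hat,
            }
        )
    if not rows:
        raise EmptyDatasetError(
            f"no (sex, cohort, year) cell reached min_cell_n={min_cell_n}"
        )
    out = pd.DataFrame(rows).sort_values(["sex", "cohort_label", "year"])
    return out.reset_index(drop=True)


def cohort_model_frame(cohorts: pd.DataFrame) -> pd.DataFrame:
    """Map cohort observations to the covariate frame the models consume."""
    return pd.DataFrame(
        {
            "sex": cohorts["sex"].astype(float),
            "age": cohorts["mean_age"].astype(float),
            "year_c": cohorts["year_c"].astype(float),
            "mu": cohorts["mu_hat"].astype(float),
            "mu_hat": cohorts["mu_hat"].astype(float),
            "sigma_hat": cohorts["sigma_hat"].astype(float),
        }
    )


def write_cohort_csv(cohorts: pd.DataFrame, path) -> None:
    cols = ["cohort_label", "year", "year_c", "sex", "mean_age", "n", "mu_hat", "sigma_hat"]
    cohorts[cols].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"cohort_label", "year", "year_c", "sex", "mean_age", "n", "mu_hat", "sigma_hat"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
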