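"""BMI-category prevalence projection with parameter uncertainty.

Selected mu and sigma models imply, for every (sex, age, year), a lognormal
BMI distribution; five-category prevalences are CDF differences at the
category cut-points. Cell prevalences are aggregated over an age/sex
population table by count-weighted means, and 95% intervals come from
re-projecting under multivariate-normal draws of each model's coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .terms import make_frame

SIGMA_FLOOR = 0.01


@dataclass(frozen=True)
class BMICategoryScheme:
    """Ordered cut-points defining the five categories.

    Intervals are left-closed/right-open at interior cut-points: BMI 25.0
    is Overweight, 18.5 is Healthy weight, 35.0 is Very obese. ``at_risk``
    is everything at or above the first at-risk cut-point (default 25).
    """

    cuts: tuple[float, ...] = (18.5, 25.0, 30.0, 35.0)
    names: tuple[str, ...] = (
        "underweight",
        "healthy",
        "overweight",
        "obese",
        "very_obese",
    )
    at_risk_names: tuple[str, ...] = ("overweight", "obese", "very_obese")

    def __post_init__(self):
        if list(self.cuts) != sorted(self.cuts) or len(set(self.cuts)) != len(self.cuts):
            raise ValueError("cut-points must be strictly increasing")
        if len(self.names) != len(self.cuts) + 1:
            raise ValueError("need exactly one more category than cut-points")


DEFAULT_SCHEME = BMICategoryScheme()


@dataclass
class UncertaintyConfig:
    n_draws: int = 1000
    seed: int = 0
    level: float = 0.95

    def __post_init__(self):
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")


def predict_mu_sigma(mu_model, sigma_model, sex, age, year):
    """Two-step prediction: mu first, then sigma with mu as a covariate.

    Sigma predictions at or below zero are floored at a small positive
    bound with a warning — polynomial shape models can go negative under
    extrapolation.
    """
    frame = make_frame(sex, age, year)
    mu = mu_model.predict(frame)
    frame["mu"] = mu
    sigma = sigma_model.predict(frame)
    bad = sigma <= 0
    if np.any(bad):
        warnings.warn(
            f"sigma model predicted <= 0 for {int(bad.sum())} cells; "
            f"floored at {SIGMA_FLOOR}",
            stacklevel=2,
        )
        sigma = np.where(bad, SIGMA_FLOOR, sigma)
    return mu, sigma


def category_prevalence(mu, sigma, scheme: BMICategoryScheme = DEFAULT_SCHEME):
    """Lognormal CDF differences at the cut-points; rows sum to 1.

    ``mu``/``sigma`` broadcast; output has one trailing axis of length 5.
    """
    mu, sigma = np.broadcast_arrays(
        np.asarray(mu, dtype=float), np.asarray(sigma, dtype=float)
    )
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    z = (np.log(scheme.cuts)[..., :] - mu[..., None]) / sigma[..., None]
    cdf = stats.norm.cdf(z)
    full = np.concatenate(
        [np.zeros_like(mu)[..., None], cdf, np.ones_like(mu)[..., None]], axis=-1
    )
    return np.diff(full, axis=-1)


def at_risk(prevalence, scheme: BMICategoryScheme = DEFAULT_SCHEME):
    """Proportion in the at-risk categories (BMI >= 25 by default)."""
    prev = np.asarray(prevalence, dtype=float)
    idx = [scheme.names.index(n) for n in scheme.at_risk_names]
    return prev[..., idx].sum(axis=-1)


class CoverageError(KeyError):
    """The population table lacks a required (year, sex, age) cell."""


def _merge_population(cells: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    merged = cells.merge(population, on=["year", "sex", "age"], how="left")
    if merged["count"].isna().any():
        missing = merged.loc[merged["count"].isna(), ["year", "sex", "age"]]
        first = missing.iloc[0]
        raise CoverageError(
            f"population table lacks {len(missing)} cells, e.g. "
            f"(year={int(first['year'])}, sex={int(first['sex'])}, age={int(first['age'])})"
        )
    return merged


def aggregate(
    cells: pd.DataFrame,
    population: pd.DataFrame,
    grouping: tuple[str, ...] = ("year", "sex"),
    scheme: BMICategoryScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Population-count-weighted mean prevalence per group.

    ``cells`` must carry single-age rows (year, sex, age, one column per
    category); ``grouping`` is a subset of {year, sex, age_group}.
    """
    merged = _merge_population(cells, population)
    cats = list(scheme.names)

    def _agg(g):
        w = g["count"].to_numpy(dtype=float)
        w = w / w.sum()
        out = {c: float(np.dot(w, g[c])) for c in cats}
        out["count"] = float(g["count"].sum())
        return pd.Series(out)

    res = merged.groupby(list(grouping)).apply(_agg, include_groups=False)
    return res.reset_index()


def project(
    mu_model,
    sigma_model,
    years,
    ages,
    population: pd.DataFrame | None = None,
    scheme: BMICategoryScheme = DEFAULT_SCHEME,
    horizon: int = 2035,
) -> pd.DataFrame:
    """Deterministic five-category forecast per (year, sex, age) cell.

    Returns single-age rows; if ``population`` is given, sex-specific and
    both-sex aggregated rows (age = -1) are appended with their weights.
    Warns when projecting beyond the declared horizon.
    """
    years = np.asarray(years, dtype=int)
    ages = np.asarray(ages, dtype=int)
    if years.max() > horizon:
        warnings.warn(
            f"projecting beyond the declared horizon {horizon}", stacklevel=2
        )
    yy, ss, aa = np.meshgrid(years, [0, 1], ages, indexing="ij")
    mu, sigma = predict_mu_sigma(mu_model, sigma_model, ss.ravel(), aa.ravel(), yy.ravel())
    prev = category_prevalence(mu, sigma, scheme)
    cells = pd.DataFrame(
        {"year": yy.ravel(), "sex": ss.ravel(), "age": aa.ravel()}
    )
    for i, name in enumerate(scheme.names):
        cells[name] = prev[:, i]
    cells["at_risk"] = at_risk(prev, scheme)
    if population is None:
        return cells
    agg_rows = []
    for grouping in (("year", "sex"), ("year",)):
        agg = aggregate(cells, population, grouping, scheme)
        if "sex" not in agg.columns:
            agg["sex"] = -1
        agg["age"] = -1
        agg["at_risk"] = agg[list(scheme.at_risk_names)].sum(axis=1)
        agg_rows.append(agg)
    return pd.concat([cells] + agg_rows, ignore_index=True)


def _psd_covariance(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    cov = (cov + cov.T) / 2
    w, v = np.linalg.eigh(cov)
    if w.min() < 0:
        warnings.warn(
            "covariance not positive semi-definite; clipping negative eigenvalues",
            stacklevel=3,
        )
        w = np.clip(w, 0.0, None)
        cov = v @ np.diag(w) @ v.T
    return cov


def _draw_coefs(model, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    cov = _psd_covariance(model.cov_)
    return rng.multivariate_normal(model.coef_, cov, size=n_draws, method="svd")


def uncertainty(
    mu_model,
    sigma_model,
    years,
    ages,
    population: pd.DataFrame,
    scheme: BMICategoryScheme = DEFAULT_SCHEME,
    ucfg: UncertaintyConfig | None = None,
) -> pd.DataFrame:
    """Interval-augmented forecast by multivariate-normal parameter resampling.

    Coefficients of the mu and sigma models are drawn independently from
    N(estimate, covariance); the full projection is recomputed per draw.
    Point estimates are draw means; intervals are the 2.5/97.5 percentiles
    (for the default 95% level). Long output: one row per
    (year, sex, age, category) with mean/lower/upper, where sex = -1 marks
    the both-sex aggregate and age = -1 an aggregated row; the plug-in
    deterministic projection is joined as column ``plugin``.
    """
    ucfg = ucfg or UncertaintyConfig()
    rng = np.random.default_rng(ucfg.seed)
    mu_draws = _draw_coefs(mu_model, ucfg.n_draws, rng)
    sigma_draws = _draw_coefs(sigma_model, ucfg.n_draws, rng)

    from .models import model_from_dict, model_to_dict  # cheap shallow clones

    mu_payload = model_to_dict(mu_model)
    sigma_payload = model_to_dict(sigma_model)

    stack = []
    for d in range(ucfg.n_draws):
        m = model_from_dict(mu_payload)
        m.coef_ = mu_draws[d]
        s = model_from_dict(sigma_payload)
        s.coef_ = sigma_draws[d]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fc = project(m, s, years, ages, population, scheme)
        stack.append(fc[list(scheme.names) + ["at_risk"]].to_numpy(dtype=np.float32))
    cube = np.stack(stack)  # draws x rows x categories

    base = project(mu_model, sigma_model, years, ages, population, scheme)
    alpha = (1.0 - ucfg.level) / 2
    lo = np.quantile(cube, alpha, axis=0)
    hi = np.quantile(cube, 1 - alpha, axis=0)
    mean = cube.mean(axis=0)

    cats = list(scheme.names) + ["at_risk"]
    rows = []
    for i, cat in enumerate(cats):
        part = base[["year", "sex", "age"]].copy()
        part["category"] = cat
        part["plugin"] = base[cat].to_numpy()
        part["prevalence"] = mean[:, i]
        part["lower"] = lo[:, i]
        part["upper"] = hi[:, i]
        rows.append(part)
    return pd.concat(rows, ignore_index=True)


def write_forecast_csv(forecast: pd.DataFrame, path) -> None:
    forecast.to_csv(path, index=False)
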