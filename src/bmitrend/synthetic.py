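"""Survey-like microdata and population-table generators.

Emulates the shape of an annual measurement survey of adults: per survey
year a sample of adults with sex, integer age and a measured BMI, where
log(BMI) is normal with position mu and shape sigma that vary smoothly in
sex, age and calendar year. Fitting the pipeline to generated data with
known coefficient surfaces makes every downstream stage testable by
parameter recovery, without any external download.

Not emulated: multi-stage sampling design, clustering, non-response
weighting, or the real survey's age pyramid (ages are uniform by default;
pass ``age_sampler`` to plug in a different age distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference
from .terms import evaluate_surface, make_frame


class ConfigurationError(ValueError):
    """The generator configuration violates an invariant."""


@dataclass
class GeneratorConfig:
    """Generating truth and sampling plan for one synthetic survey.

    ``mu_truth`` and ``sigma_truth`` map term names (see ``terms.TERM_ORDER``,
    plus the exponential triple a/b/c) to coefficients; mu-terms inside
    ``sigma_truth`` are evaluated at the true mu for the same covariates.
    Defaults generate 24 survey years at the scale of the England analysis
    (~400 sex-specific cohort-year cells downstream).
    """

    years: Sequence[int] = tuple(range(1991, 2015))
    n_per_year: int = 8000
    age_range: tuple[int, int] = (18, 95)
    sex_ratio: float = 0.5
    mu_truth: Mapping[str, float] = field(
        default_factory=lambda: dict(reference.LINEAR_MU)
    )
    sigma_truth: Mapping[str, float] = field(
        default_factory=lambda: dict(reference.LINEAR_SIGMA)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.years) == 0:
            raise ConfigurationError("years must be non-empty")
        if self.n_per_year < 1:
            raise ConfigurationError("n_per_year must be >= 1")
        lo, hi = self.age_range
        if lo < 18:
            raise ConfigurationError("age_range minimum must be >= 18 (adults)")
        if hi < lo:
            raise ConfigurationError("age_range must be (min, max) with min <= max")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        self._check_sigma_positive()

    def _grid(self) -> pd.DataFrame:
        lo, hi = self.age_range
        ages = np.arange(lo, hi + 1)
        sex, age, year = np.meshgrid([0, 1], ages, list(self.years), indexing="ij")
        return make_frame(sex.ravel(), age.ravel(), year.ravel())

    def _check_sigma_positive(self) -> None:
        grid = self._grid()
        grid["mu"] = evaluate_surface(self.mu_truth, grid)
        sigma = evaluate_surface(self.sigma_truth, grid)
        bad = sigma <= 0
        if np.any(bad):
            worst = grid.loc[np.argmin(sigma)]
            raise ConfigurationError(
                "sigma_truth is non-positive for "
                f"{int(bad.sum())} covariate combinations, e.g. sex={worst['sex']:.0f}, "
                f"age={worst['age']:.0f}, year={worst['year_c'] + 2003:.0f} "
                f"(sigma={sigma.min():.4g})"
            )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ConfigurationError("generator config must set a seed")
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)


def truth_parameters(config: GeneratorConfig, sex, age, year):
    """Exact generating (mu, sigma) for the given covariates.

    Oracle access for recovery tests: returns precisely what
    ``generate_survey`` draws from at those covariates.
    """
    sex_a = np.asarray(sex)
    age_a = np.asarray(age)
    year_a = np.asarray(year)
    lo, hi = config.age_range
    if np.any((age_a < lo) | (age_a > hi)):
        raise ValueError(f"age outside configured range [{lo}, {hi}]")
    if not np.all(np.isin(year_a, list(config.years))):
        raise ValueError("year not among the configured survey years")
    if not np.all(np.isin(sex_a, [0, 1])):
        raise ValueError("sex must be coded 1 (male) or 0 (female)")
    frame = make_frame(sex, age, year)
    mu = evaluate_surface(config.mu_truth, frame)
    frame["mu"] = mu
    sigma = evaluate_surface(config.sigma_truth, frame)
    scalar = np.isscalar(sex) and np.isscalar(age) and np.isscalar(year)
    if scalar:
        return float(mu[0]), float(sigma[0])
    return mu, sigma


def generate_survey(
    config: GeneratorConfig,
    age_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Draw one synthetic survey: columns ``year, age, sex, bmi``.

    For each year, ``n_per_year`` adults: age uniform over ``age_range``
    (unless ``age_sampler`` is given), sex Bernoulli(sex_ratio), and
    BMI = exp(Normal(mu, sigma)) at the record's covariates. A single RNG
    stream seeded from ``config.seed`` makes output byte-identical across
    runs of the same config.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    chunks = []
    for year in config.years:
        n = config.n_per_year
        if age_sampler is None:
            age = rng.integers(lo, hi + 1, size=n)
        else:
            age = np.asarray(age_sampler(rng, n))
            if np.any((age < lo) | (age > hi)):
                raise ConfigurationError("age_sampler produced ages outside age_range")
        sex = (rng.random(n) < config.sex_ratio).astype(int)
        frame = make_frame(sex, age, np.full(n, year))
        mu = evaluate_surface(config.mu_truth, frame)
        frame["mu"] = mu
        sigma = evaluate_surface(config.sigma_truth, frame)
        bmi = np.exp(rng.normal(mu, sigma))
        chunks.append(
            pd.DataFrame({"year": int(year), "age": age, "sex": sex, "bmi": bmi})
        )
    return pd.concat(chunks, ignore_index=True)


def write_survey_csv(records: pd.DataFrame, path) -> None:
    """Write survey CSV with header ``year,age,sex,bmi`` (BMI to 4 dp)."""
    out = records[["year", "age", "sex", "bmi"]].copy()
    out["bmi"] = out["bmi"].round(4)
    out.to_csv(path, index=False)


def read_survey_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["year", "age", "sex", "bmi"]
    if list(df.columns) != expected:
        raise ValueError(f"survey CSV must have header {','.join(expected)}")
    return df


def generate_population_weights(
    years: Sequence[int],
    age_range: tuple[int, int] = (18, 100),
    growth_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic age/sex population table: columns ``year, sex, age, count``.

    A stand-in for an official principal population projection. The age
    profile is a smooth adult pyramid (flat through working ages, declining
    beyond ~70) with fixed per-age jitter, scaled by (1+growth_rate)^t so
    growth_rate 0 yields an identical profile in every year.
    """
    if len(years) == 0:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(seed)
    lo, hi = age_range
    ages = np.arange(lo, hi + 1)
    # smooth survival-like taper; jitter is per-age, shared across years
    base = 70_000.0 * np.exp(-np.clip(ages - 70, 0, None) ** 2 / (2 * 14.0**2))
    jitter = rng.lognormal(0.0, 0.03, size=(2, ages.size))
    rows = []
    y0 = min(years)
    for year in years:
        scale = (1.0 + growth_rate) ** (year - y0)
        for sex in (0, 1):
            counts = np.maximum(base * jitter[sex] * scale, 1.0)
            rows.append(
                pd.DataFrame(
                    {
                        "year": int(year),
                        "sex": sex,
                        "age": ages,
                        "count": np.round(counts).astype(int),
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    return table[["year", "sex", "age", "count"]]


def read_population_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["year", "sex", "age", "count"]
    if list(df.columns) != expected:
        raise ValueError(f"population CSV must have header {','.join(expected)}")
    if df.duplicated(["year", "sex", "age"]).any():
        raise ValueError("population CSV has duplicate (year, sex, age) keys")
    if (df["count"] < 0).any():
        raise ValueError("population counts must be >= 0")
    return df
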