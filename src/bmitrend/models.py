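"""Candidate trend models of the log-BMI position (mu) and shape (sigma).

Two families share one covariate grammar:

* linear  — polynomial in centred year: Y = b0 + b_year*year + b_year2*year^2
  + sex/age terms; extrapolated, it can peak and decline (best case).
* nonlinear — exponential year structure: Y = a - b*exp(-c*year) + sex/age
  terms; extrapolated, it flattens toward the asymptote a (worst case).

Shape (sigma) candidates may additionally include the position mu and mu^2
as covariates — the second step of the two-step distributional regression.
Estimators follow the scikit-learn protocol: ``fit(X, y)`` on a covariate
frame (columns sex, age, year_c and mu for sigma models), fitted attributes
with trailing underscores, ``predict(X)``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .terms import (
    EXP_PARAMS,
    TERM_ORDER,
    evaluate_surface,
    exponential_year_trend,
    term_column,
)


class SingularDesignError(ValueError):
    """Design matrix is rank deficient for this candidate on these data."""


class ConvergenceError(RuntimeError):
    """Non-linear least squares failed to converge from every start."""


# ---------------------------------------------------------------------------
# candidate grammar


@dataclass(frozen=True)
class CandidateModel:
    """A declared term set for one outcome and family.

    ``terms`` is canonically ordered. Linear candidates carry explicit
    year/year2 terms; nonlinear candidates carry the pseudo-terms a, b, c
    (the exponential triple) instead of a year polynomial and intercept.
    """

    outcome: str  # "mu" | "sigma"
    family: str  # "linear" | "nonlinear"
    terms: tuple[str, ...]

    def __post_init__(self):
        if self.outcome not in ("mu", "sigma"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.family not in ("linear", "nonlinear"):
            raise ValueError(f"unknown family {self.family!r}")
        order = _canonical_order(self.family)
        object.__setattr__(
            self, "terms", tuple(sorted(self.terms, key=order.index))
        )
        if self.outcome == "mu" and any(t in ("mu", "mu2") for t in self.terms):
            raise ValueError("mu-terms are only permitted for sigma outcomes")

    @property
    def id(self) -> str:
        return f"{self.outcome}~{self.family}:" + "+".join(self.terms)

    @property
    def n_params(self) -> int:
        return len(self.terms)

    @property
    def linear_terms(self) -> tuple[str, ...]:
        """Terms entering the design matrix (excludes the exponential triple)."""
        return tuple(t for t in self.terms if t not in EXP_PARAMS)


def _canonical_order(family: str) -> list[str]:
    if family == "linear":
        return list(TERM_ORDER)
    return list(EXP_PARAMS) + [t for t in TERM_ORDER if t not in ("intercept", "year", "year2")]


#: mandatory core per family (intercept/exponential triple, sex, age, year structure)
_CORE = {
    "linear": ("intercept", "sex", "age", "year"),
    "nonlinear": ("a", "b", "c", "sex", "age"),
}

#: optional pool per family; each term maps to the terms it requires (hierarchy)
_OPTIONAL = {
    "linear": {
        "age2": (),
        "year2": (),
        "sex:age": (),
        "sex:age2": ("sex:age", "age2"),
        "age:year": (),
        "age:year2": ("age:year", "year2"),
        "sex:year": (),
        "mu": (),
        "mu2": ("mu",),
    },
    # the exponential family carries its year structure in (a, b, c); no
    # year polynomial or year interactions are offered
    "nonlinear": {
        "age2": (),
        "sex:age": (),
        "sex:age2": ("sex:age", "age2"),
        "mu": (),
        "mu2": ("mu",),
    },
}


def enumerate_candidates(
    outcome: str,
    family: str,
    optional_terms: Sequence[str] | None = None,
) -> list[CandidateModel]:
    """All hierarchy-respecting candidates for one (outcome, family).

    Every candidate contains the mandatory core; ``optional_terms`` restricts
    the optional pool (None = full pool; empty = core only). The list is
    deterministic, duplicate-free, and canonically ordered.
    """
    pool = dict(_OPTIONAL[family])
    if outcome == "mu":
        pool = {k: v for k, v in pool.items() if k not in ("mu", "mu2")}
    if optional_terms is not None:
        # validate against the full grammar; terms inapplicable to this
        # (outcome, family) are silently dropped so one restriction list
        # can serve all four contests
        unknown = set(optional_terms) - set(_OPTIONAL["linear"])
        if unknown:
            raise ValueError(f"terms not in the optional pool: {sorted(unknown)}")
        pool = {k: v for k, v in pool.items() if k in optional_terms}
    names = list(pool)
    out = []
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            chosen = set(combo)
            if all(set(pool[t]) <= chosen for t in combo):
                out.append(
                    CandidateModel(outcome, family, _CORE[family] + tuple(combo))
                )
    out.sort(key=lambda c: (c.n_params, c.id))
    return out


def design_matrix(
    candidate: CandidateModel, frame: pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    """Predictor matrix for the candidate's linear terms, in canonical order."""
    names = list(candidate.linear_terms)
    cols = [term_column(t, frame) for t in names]
    X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    return X, names


def response_vector(candidate: CandidateModel, frame: pd.DataFrame) -> np.ndarray:
    col = "mu_hat" if candidate.outcome == "mu" else "sigma_hat"
    if col not in frame:
        raise KeyError(f"frame lacks response column {col!r}")
    return np.asarray(frame[col], dtype=float)


# ---------------------------------------------------------------------------
# estimators


class _TrendModelBase(BaseEstimator):
    def __init__(self, candidate: CandidateModel | None = None):
        self.candidate = candidate

    def _frame_or_xy(self, X, y):
        if y is None:
            y = response_vector(self.candidate, X)
        return X, np.asarray(y, dtype=float)

    @property
    def coef_dict_(self) -> dict[str, float]:
        return dict(zip(self.term_names_, self.coef_))

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        return evaluate_surface(self.coef_dict_, X)

    def _finish(self, y: np.ndarray, fitted: np.ndarray) -> None:
        resid = y - fitted
        self.resid_ = resid
        self.nobs_ = int(y.size)
        self.rss_ = float(resid @ resid)
        self.df_resid_ = self.nobs_ - len(self.term_names_)


class LinearTrendModel(_TrendModelBase):
    """Ordinary least squares fit of a polynomial-in-year candidate."""

    def fit(self, X, y=None):
        if self.candidate is None or self.candidate.family != "linear":
            raise ValueError("LinearTrendModel needs a linear-family candidate")
        X, y = self._frame_or_xy(X, y)
        mat, names = design_matrix(self.candidate, X)
        if y.size <= mat.shape[1]:
            raise ValueError("need more observations than parameters")
        if np.linalg.matrix_rank(mat) < mat.shape[1]:
            raise SingularDesignError(
                f"design matrix rank deficient for {self.candidate.id}"
            )
        res = sm.OLS(y, pd.DataFrame(mat, columns=names)).fit()
        self.term_names_ = names
        self.coef_ = res.params.to_numpy()
        self.bse_ = res.bse.to_numpy()
        self.cov_ = res.cov_params().to_numpy()
        self.tvalues_ = res.tvalues.to_numpy()
        self.pvalues_ = res.pvalues.to_numpy()
        self.result_ = res
        self._finish(y, res.fittedvalues)
        return self


class ExponentialTrendModel(_TrendModelBase):
    """Least-squares fit of Y = a - b*exp(-c*year_c) + linear terms.

    Fitting profiles the rate c (for fixed c the model is linear in every
    other coefficient, solved by least squares) over a multistart grid,
    then refines all parameters jointly by Levenberg-Marquardt. Standard
    errors come from the Jacobian-based covariance at the optimum. A fitted
    c <= 0 means the year trend is not flattening; it is reported with a
    warning flag (``nonflattening_``), not an error.
    """

    #: profiled-c starts; negative rates are included because a shape model
    #: can legitimately have a growing exponential term
    C_STARTS = (0.01, 0.05, 0.1, 0.5, -0.05, -0.2)

    def __init__(self, candidate: CandidateModel | None = None, xtol: float = 1e-12):
        super().__init__(candidate)
        self.xtol = xtol

    def fit(self, X, y=None):
        if self.candidate is None or self.candidate.family != "nonlinear":
            raise ValueError("ExponentialTrendModel needs a nonlinear-family candidate")
        X, y = self._frame_or_xy(X, y)
        year_c = np.asarray(X["year_c"], dtype=float)
        Xlin, lin_names = design_matrix(self.candidate, X)
        k = 3 + Xlin.shape[1]
        if y.size <= k:
            raise ValueError("need more observations than parameters")

        best = None
        for c0 in self.C_STARTS:
            theta0, rss0 = _profile_solve(c0, year_c, Xlin, y)
            if theta0 is None:
                continue
            try:
                sol = least_squares(
                    _residuals,
                    theta0,
                    args=(year_c, Xlin, y),
                    method="lm",
                    xtol=self.xtol,
                    ftol=self.xtol,
                    gtol=self.xtol,
                )
            except Exception:
                continue
            rss = float(sol.fun @ sol.fun)
            if best is None or rss < best[1] - 1e-15:
                best = (sol, rss)
        if best is None:
            raise ConvergenceError(
                f"no start converged for {self.candidate.id}"
            )
        sol, rss = best
        theta = sol.x
        self.term_names_ = list(EXP_PARAMS) + lin_names
        self.coef_ = theta.copy()
        fitted = y - _residuals(theta, year_c, Xlin, y)
        self._finish(y, fitted)
        # Jacobian-based covariance; pinv guards the near-flat c direction
        J = sol.jac
        s2 = self.rss_ / max(self.df_resid_, 1)
        self.cov_ = s2 * np.linalg.pinv(J.T @ J)
        self.bse_ = np.sqrt(np.clip(np.diag(self.cov_), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.tvalues_ = np.where(self.bse_ > 0, self.coef_ / self.bse_, np.nan)
        from scipy import stats as _st

        self.pvalues_ = 2 * _st.t.sf(np.abs(self.tvalues_), self.df_resid_)
        self.nonflattening_ = bool(theta[2] <= 0)
        return self


def _residuals(theta, year_c, Xlin, y):
    a, b, c = theta[:3]
    pred = exponential_year_trend(a, b, c, year_c)
    if Xlin.shape[1]:
        pred = pred + Xlin @ theta[3:]
    return pred - y


def _profile_solve(c, year_c, Xlin, y):
    """For fixed rate c, solve the remaining coefficients by least squares.

    Returns (full theta with the given c, rss) or (None, inf) when the
    profiled design is rank deficient (e.g. c = 0 makes the exp column
    collinear with the intercept).
    """
    e = exponential_year_trend(0.0, -1.0, c, year_c)  # = exp(-c*year_c)
    M = np.column_stack([np.ones_like(y), -e, Xlin])
    beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < M.shape[1]:
        return None, np.inf
    resid = y - M @ beta
    theta = np.concatenate([[beta[0], beta[1], c], beta[2:]])
    return theta, float(resid @ resid)


DEFAULT_C_GRID = np.linspace(-0.5, 1.0, 31)


def profile_exponential_fit(
    year_c: np.ndarray,
    Xlin: np.ndarray,
    y: np.ndarray,
    c_grid: np.ndarray = DEFAULT_C_GRID,
) -> tuple[np.ndarray, float]:
    """Variable-projection fit on raw arrays: grid over c, then local refine.

    Returns (theta = [a, b, c, beta...], rss). Raises SingularDesignError
    when the profiled design is rank deficient at every grid point.
    """
    from scipy.optimize import minimize_scalar

    rss = np.array([_profile_solve(c, year_c, Xlin, y)[1] for c in c_grid])
    if not np.any(np.isfinite(rss)):
        raise SingularDesignError("profiled design singular over the whole c grid")
    i = int(np.nanargmin(np.where(np.isfinite(rss), rss, np.nan)))
    lo = c_grid[max(i - 1, 0)]
    hi = c_grid[min(i + 1, len(c_grid) - 1)]
    res = minimize_scalar(
        lambda c: _profile_solve(c, year_c, Xlin, y)[1],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    c_best = res.x if res.fun <= rss[i] else c_grid[i]
    theta, best_rss = _profile_solve(c_best, year_c, Xlin, y)
    if theta is None:
        theta, best_rss = _profile_solve(c_grid[i], year_c, Xlin, y)
    return theta, best_rss


def fit_nonlinear_fast(
    candidate: CandidateModel,
    frame: pd.DataFrame,
    y: np.ndarray,
    c_grid: np.ndarray = DEFAULT_C_GRID,
) -> tuple[np.ndarray, list[str], float]:
    """Variable-projection fit used inside the cross-validation loop."""
    year_c = np.asarray(frame["year_c"], dtype=float)
    Xlin, lin_names = design_matrix(candidate, frame)
    theta, rss = profile_exponential_fit(year_c, Xlin, y, c_grid)
    return theta, list(EXP_PARAMS) + lin_names, rss


# ---------------------------------------------------------------------------
# wrappers and statistics


def make_model(candidate: CandidateModel):
    cls = LinearTrendModel if candidate.family == "linear" else ExponentialTrendModel
    return cls(candidate)


def fit_linear(candidate: CandidateModel, observations: pd.DataFrame) -> LinearTrendModel:
    return LinearTrendModel(candidate).fit(observations)


def fit_nonlinear(
    candidate: CandidateModel, observations: pd.DataFrame
) -> ExponentialTrendModel:
    return ExponentialTrendModel(candidate).fit(observations)


def predict(fitted: _TrendModelBase, covariates: pd.DataFrame) -> np.ndarray:
    return fitted.predict(covariates)


def fit_stats(fitted: _TrendModelBase) -> dict:
    """Goodness-of-fit summary.

    Gaussian log-likelihood at the MLE variance rss/n; AIC = 2k - 2*loglik
    and BIC = k*ln(n) - 2*loglik with k the number of mean parameters;
    deviance = residual sum of squares. R-squared and the F-statistic are
    reported for the linear family only (None for the exponential family,
    where the usual decomposition does not apply).
    """
    n = fitted.nobs_
    k = len(fitted.term_names_)
    rss = fitted.rss_
    df_resid = fitted.df_resid_
    loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    out = {
        "resid_se": float(np.sqrt(rss / df_resid)),
        "loglik": float(loglik),
        "aic": float(2 * k - 2 * loglik),
        "bic": float(k * np.log(n) - 2 * loglik),
        "deviance": float(rss),
        "df_model": k - (1 if fitted.candidate.family == "linear" else 0),
        "df_resid": int(df_resid),
        "n_obs": n,
    }
    if isinstance(fitted, LinearTrendModel) and hasattr(fitted, "result_"):
        res = fitted.result_
        out.update(
            r_squared=float(res.rsquared),
            adj_r_squared=float(res.rsquared_adj),
            f_statistic=float(res.fvalue),
            f_pvalue=float(res.f_pvalue),
        )
    else:
        out.update(r_squared=None, adj_r_squared=None, f_statistic=None, f_pvalue=None)
    return out


def model_to_dict(fitted: _TrendModelBase) -> dict:
    return {
        "outcome": fitted.candidate.outcome,
        "family": fitted.candidate.family,
        "terms": list(fitted.candidate.terms),
        "coef": {t: float(v) for t, v in zip(fitted.term_names_, fitted.coef_)},
        "bse": {t: float(v) for t, v in zip(fitted.term_names_, fitted.bse_)},
        "cov": np.asarray(fitted.cov_).tolist(),
        "stats": fit_stats(fitted),
    }


def model_from_dict(payload: Mapping) -> _TrendModelBase:
    cand = CandidateModel(
        payload["outcome"], payload["family"], tuple(payload["terms"])
    )
    model = make_model(cand)
    model.term_names_ = list(payload["coef"].keys())
    model.coef_ = np.array(list(payload["coef"].values()), dtype=float)
    model.bse_ = np.array(list(payload["bse"].values()), dtype=float)
    model.cov_ = np.array(payload["cov"], dtype=float)
    stats_ = payload["stats"]
    model.nobs_ = int(stats_["n_obs"])
    model.df_resid_ = int(stats_["df_resid"])
    model.rss_ = float(stats_["deviance"])
    return model


def save_models_json(models: Mapping[str, _TrendModelBase], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: model_to_dict(m) for k, m in models.items()}, fh, indent=1)


def load_models_json(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    return {k: model_from_dict(v) for k, v in payload.items()}


def coefficients_table(fitted: _TrendModelBase) -> pd.DataFrame:
    """Estimate / SE / t / p table, one row per term."""
    return pd.DataFrame(
        {
            "term": fitted.term_names_,
            "estimate": fitted.coef_,
            "std_error": fitted.bse_,
            "t_value": fitted.tvalues_,
            "p_value": fitted.pvalues_,
        }
    )
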