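"""Term grammar shared by the trend surfaces, design matrices and generators.

Covariates are always ``sex`` (1 = male, 0 = female), ``age`` (years),
``year_c`` (calendar year centred so that 2003 maps to 0) and, for shape
(sigma) models only, ``mu`` — the position of the log-BMI distribution.
The exponential-family year structure is carried by the pseudo-terms
``a``, ``b``, ``c`` encoding ``a - b * exp(-c * year_c)``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

YEAR_ZERO = 2003

#: exponential-family year-trend parameters, in canonical order
EXP_PARAMS = ("a", "b", "c")

#: canonical ordering of every linear term the grammar knows
TERM_ORDER = (
    "intercept",
    "sex",
    "age",
    "year",
    "age2",
    "year2",
    "sex:age",
    "sex:age2",
    "age:year",
    "age:year2",
    "sex:year",
    "mu",
    "mu2",
)

#: terms only meaningful for shape (sigma) outcomes
MU_TERMS = ("mu", "mu2")


def center_year(year) -> np.ndarray:
    """Map calendar year to the centred scale (2003 -> 0)."""
    return np.asarray(year, dtype=float) - YEAR_ZERO


class MissingCovariateError(KeyError):
    """A term requires a covariate column the frame does not carry."""


def _col(frame, name: str, term: str) -> np.ndarray:
    try:
        return np.asarray(frame[name], dtype=float)
    except KeyError:
        raise MissingCovariateError(
            f"term {term!r} needs covariate column {name!r}"
        ) from None


def term_column(term: str, frame) -> np.ndarray:
    """Evaluate one linear term on a frame with sex/age/year_c (and mu) columns."""
    if term == "intercept":
        n = len(frame["sex"]) if not hasattr(frame, "index") else len(frame)
        return np.ones(n)
    if term == "sex":
        return _col(frame, "sex", term)
    if term == "age":
        return _col(frame, "age", term)
    if term == "year":
        return _col(frame, "year_c", term)
    if term == "age2":
        return _col(frame, "age", term) ** 2
    if term == "year2":
        return _col(frame, "year_c", term) ** 2
    if term == "sex:age":
        return _col(frame, "sex", term) * _col(frame, "age", term)
    if term == "sex:age2":
        return _col(frame, "sex", term) * _col(frame, "age", term) ** 2
    if term == "age:year":
        return _col(frame, "age", term) * _col(frame, "year_c", term)
    if term == "age:year2":
        return _col(frame, "age", term) * _col(frame, "year_c", term) ** 2
    if term == "sex:year":
        return _col(frame, "sex", term) * _col(frame, "year_c", term)
    if term == "mu":
        return _col(frame, "mu", term)
    if term == "mu2":
        return _col(frame, "mu", term) ** 2
    raise ValueError(f"unknown term {term!r}")


# exponent clipped so extreme rates during optimisation cannot overflow
_EXP_CLIP = 50.0


def exponential_year_trend(a: float, b: float, c: float, year_c) -> np.ndarray:
    """a - b * exp(-c * year_c), the flattening-toward-asymptote year structure."""
    z = np.clip(-c * np.asarray(year_c, dtype=float), -_EXP_CLIP, _EXP_CLIP)
    return a - b * np.exp(z)


def evaluate_surface(coefs: Mapping[str, float], frame) -> np.ndarray:
    """Evaluate a coefficient mapping on a covariate frame.

    ``coefs`` maps term names (any of TERM_ORDER) and optionally the
    exponential triple a/b/c to coefficients. Works for both families:
    a plain polynomial surface has no a/b/c entries.
    """
    has_exp = any(k in coefs for k in EXP_PARAMS)
    if has_exp:
        out = exponential_year_trend(
            coefs.get("a", 0.0),
            coefs.get("b", 0.0),
            coefs.get("c", 0.0),
            _col(frame, "year_c", "c"),
        )
    else:
        out = 0.0
    for term, beta in coefs.items():
        if term in EXP_PARAMS:
            continue
        out = out + beta * term_column(term, frame)
    return np.asarray(out, dtype=float)


def make_frame(sex, age, year, mu=None) -> pd.DataFrame:
    """Broadcast covariates into the standard model frame (year is calendar year)."""
    sex, age, year = np.broadcast_arrays(
        np.asarray(sex, dtype=float), np.asarray(age, dtype=float), np.asarray(year)
    )
    frame = pd.DataFrame(
        {"sex": sex.ravel(), "age": age.ravel(), "year_c": center_year(year).ravel()}
    )
    if mu is not None:
        frame["mu"] = np.broadcast_to(np.asarray(mu, dtype=float), sex.shape).ravel()
    return frame
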