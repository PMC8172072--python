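import numpy as np
import pandas as pd
import pytest

from bmitrend import reference
from bmitrend.cohort import (
    assign_cohorts,
    build_cohort_dataset,
    cohort_model_frame,
    filter_records,
)
from bmitrend.models import model_from_dict
from bmitrend.synthetic import GeneratorConfig, generate_survey


@pytest.fixture(scope="session")
def small_survey() -> pd.DataFrame:
    """24 survey years at modest per-year size; the workhorse fixture."""
    cfg = GeneratorConfig(years=tuple(range(1991, 2015)), n_per_year=1500, seed=42)
    return generate_survey(cfg)


@pytest.fixture(scope="session")
def cohort_frame(small_survey) -> pd.DataFrame:
    kept, _ = filter_records(small_survey)
    cohorts = build_cohort_dataset(assign_cohorts(kept))
    return cohort_model_frame(cohorts)


def reference_model(outcome: str, family: str, coefs: dict, bse: dict | None = None):
    """Wrap a published coefficient set as a fitted model object.

    Zero covariance unless per-term standard errors are supplied (then the
    covariance is diagonal) — enough for deterministic projection tests.
    """
    bse = bse or {k: 0.0 for k in coefs}
    cov = np.diag([bse[k] ** 2 for k in coefs])
    return model_from_dict(
        {
            "outcome": outcome,
            "family": family,
            "terms": list(coefs),
            "coef": dict(coefs),
            "bse": dict(bse),
            "cov": cov.tolist(),
            "stats": {"n_obs": 400, "df_resid": 400 - len(coefs), "deviance": 0.1},
        }
    )


@pytest.fixture(scope="session")
def england_models() -> dict:
    return {
        "mu_linear": reference_model("mu", "linear", reference.LINEAR_MU),
        "sigma_linear": reference_model("sigma", "linear", reference.LINEAR_SIGMA),
        "mu_nonlinear": reference_model("mu", "nonlinear", reference.NONLINEAR_MU),
        "sigma_nonlinear": reference_model("sigma", "nonlinear", reference.NONLINEAR_SIGMA),
    }
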