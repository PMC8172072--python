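import numpy as np
import pandas as pd
import pytest

from bmitrend import reference
from bmitrend.models import (
    CandidateModel,
    ExponentialTrendModel,
    LinearTrendModel,
    design_matrix,
    enumerate_candidates,
    fit_linear,
    fit_nonlinear,
    fit_nonlinear_fast,
    fit_stats,
    model_from_dict,
    model_to_dict,
)
from bmitrend.terms import evaluate_surface, make_frame


def _random_frame(n=400, seed=0, with_mu=True):
    rng = np.random.default_rng(seed)
    frame = make_frame(
        rng.integers(0, 2, n), rng.uniform(18, 95, n), rng.integers(1991, 2015, n)
    )
    if with_mu:
        frame["mu"] = evaluate_surface(reference.LINEAR_MU, frame)
    return frame


class TestEnumerateCandidates:
    def test_england_optimal_sets_reachable(self):
        linear_mu = {tuple(sorted(c.terms)) for c in enumerate_candidates("mu", "linear")}
        assert tuple(sorted(("intercept", "sex", "age", "year", "age2", "year2"))) in linear_mu
        nl_sigma = {frozenset(c.terms) for c in enumerate_candidates("sigma", "nonlinear")}
        assert frozenset(reference.NONLINEAR_SIGMA) in nl_sigma
        lin_sigma = {frozenset(c.terms) for c in enumerate_candidates("sigma", "linear")}
        assert frozenset(reference.LINEAR_SIGMA) in lin_sigma

    def test_mandatory_only_restriction(self):
        for outcome in ("mu", "sigma"):
            for family in ("linear", "nonlinear"):
                lst = enumerate_candidates(outcome, family, optional_terms=[])
                assert len(lst) == 1

    def test_linear_list_strictly_larger_and_unique(self):
        for outcome in ("mu", "sigma"):
            lin = enumerate_candidates(outcome, "linear")
            nl = enumerate_candidates(outcome, "nonlinear")
            assert len(lin) > len(nl)
            assert len({c.id for c in lin + nl}) == len(lin) + len(nl)

    def test_deterministic_ordering(self):
        a = [c.id for c in enumerate_candidates("sigma", "linear")]
        b = [c.id for c in enumerate_candidates("sigma", "linear")]
        assert a == b

    def test_hierarchy_respected(self):
        for c in enumerate_candidates("sigma", "linear"):
            t = set(c.terms)
            if "sex:age2" in t:
                assert {"sex:age", "age2"} <= t
            if "age:year2" in t:
                assert {"age:year", "year2"} <= t
            if "mu2" in t:
                assert "mu" in t

    def test_mu_terms_rejected_for_mu_outcome(self):
        with pytest.raises(ValueError):
            CandidateModel("mu", "linear", ("intercept", "sex", "age", "year", "mu"))


class TestDesignMatrix:
    def test_intercept_first_column_of_ones(self):
        cand = CandidateModel("mu", "linear", ("intercept", "sex", "age", "year"))
        frame = make_frame([0, 1, 1], [20, 30, 40], [2003, 2003, 2003])
        X, names = design_matrix(cand, frame)
        assert X.shape == (3, 4)
        assert names[0] == "intercept"
        assert np.all(X[:, 0] == 1.0)

    def test_mu_squared_column(self):
        cand = CandidateModel(
            "sigma", "linear", ("intercept", "sex", "age", "year", "mu", "mu2")
        )
        frame = make_frame([0, 1], [20, 30], [2000, 2010], mu=[3.1, 3.4])
        X, names = design_matrix(cand, frame)
        assert np.allclose(X[:, names.index("mu2")], X[:, names.index("mu")] ** 2)

    def test_year_centring(self):
        frame = make_frame([0], [40], [2035])
        assert frame["year_c"].iloc[0] == 32.0

    def test_missing_covariate_names_term(self):
        cand = CandidateModel("sigma", "linear", ("intercept", "sex", "age", "year", "mu"))
        frame = make_frame([0], [40], [2003])  # no mu column
        with pytest.raises(KeyError, match="mu"):
            design_matrix(cand, frame)


class TestLinearFit:
    def test_exact_fit_recovers_coefficients(self):
        frame = _random_frame(50, with_mu=False)
        y = 1.0 + 2.0 * frame["sex"].to_numpy()
        cand = CandidateModel("mu", "linear", ("intercept", "sex", "age", "year"))
        m = LinearTrendModel(cand).fit(frame, y)
        assert m.coef_dict_["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert m.coef_dict_["sex"] == pytest.approx(2.0, abs=1e-10)
        assert fit_stats(m)["r_squared"] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        frame = _random_frame(400, seed=3)
        rng = np.random.default_rng(9)
        frame["mu_hat"] = evaluate_surface(reference.LINEAR_MU, frame) + rng.normal(
            0, 0.01, len(frame)
        )
        for cand in enumerate_candidates("mu", "linear")[:10]:
            X, _ = design_matrix(cand, frame)
            y = frame["mu_hat"].to_numpy()
            beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
            m = LinearTrendModel(cand).fit(frame)
            assert np.max(np.abs(m.coef_ - beta_oracle)) < 1e-8

    def test_rank_deficiency_raises(self):
        frame = make_frame([1] * 20, np.arange(20) + 18, [2003] * 20)  # sex constant
        y = np.ones(20)
        cand = CandidateModel("mu", "linear", ("intercept", "sex", "age", "year"))
        with pytest.raises(Exception, match="rank"):
            LinearTrendModel(cand).fit(frame, y)


class TestNonlinearFit:
    def test_noiseless_recovery_to_1e6(self):
        frame = _random_frame(400, seed=1, with_mu=False)
        y = evaluate_surface(reference.NONLINEAR_MU, frame)
        cand = CandidateModel("mu", "nonlinear", tuple(reference.NONLINEAR_MU))
        m = ExponentialTrendModel(cand).fit(frame, y)
        for term, truth in reference.NONLINEAR_MU.items():
            assert m.coef_dict_[term] == pytest.approx(truth, abs=1e-6)

    def test_negative_rate_recovered_and_flagged(self):
        frame = _random_frame(400, seed=2)
        frame["mu"] = evaluate_surface(reference.NONLINEAR_MU, frame)
        y = evaluate_surface(reference.NONLINEAR_SIGMA, frame)
        cand = CandidateModel("sigma", "nonlinear", tuple(reference.NONLINEAR_SIGMA))
        m = ExponentialTrendModel(cand).fit(frame, y)
        assert m.coef_dict_["c"] == pytest.approx(reference.NONLINEAR_SIGMA["c"], abs=1e-6)
        assert m.nonflattening_ is True

    def test_b_zero_reduces_to_linear_terms_model(self):
        frame = _random_frame(300, seed=4, with_mu=False)
        truth = {"a": 3.0, "b": 0.0, "c": 0.1, "sex": 0.02, "age": 0.01}
        rng = np.random.default_rng(5)
        y = evaluate_surface(truth, frame) + rng.normal(0, 0.002, len(frame))
        nl = ExponentialTrendModel(
            CandidateModel("mu", "nonlinear", ("a", "b", "c", "sex", "age"))
        ).fit(frame, y)
        lin = LinearTrendModel(
            CandidateModel("mu", "linear", ("intercept", "sex", "age", "year"))
        ).fit(frame, y)
        # with no real year signal, predictions agree up to fitting noise
        assert np.allclose(nl.predict(frame), lin.predict(frame), atol=2e-3)

    def test_rss_beats_coarse_grid_oracle(self):
        frame = _random_frame(200, seed=6, with_mu=False)
        rng = np.random.default_rng(7)
        y = evaluate_surface(reference.NONLINEAR_MU, frame) + rng.normal(
            0, 0.01, len(frame)
        )
        cand = CandidateModel("mu", "nonlinear", tuple(reference.NONLINEAR_MU))
        m = ExponentialTrendModel(cand).fit(frame, y)
        # brute force: 3-level grids on (a, b, c), linear terms profiled out
        Xlin, _ = design_matrix(cand, frame)
        year_c = frame["year_c"].to_numpy()
        best = np.inf
        for a in (2.5, 3.0, 3.5):
            for b in (0.0, 0.03, 0.1):
                for c in (0.01, 0.1, 0.5):
                    resid0 = y - (a - b * np.exp(-c * year_c))
                    beta, *_ = np.linalg.lstsq(Xlin, resid0, rcond=None)
                    r = resid0 - Xlin @ beta
                    best = min(best, float(r @ r))
        assert m.rss_ <= best + 1e-12

    def test_fast_profile_agrees_with_full_optimiser(self):
        frame = _random_frame(250, seed=8, with_mu=False)
        rng = np.random.default_rng(9)
        y = evaluate_surface(reference.NONLINEAR_MU, frame) + rng.normal(
            0, 0.005, len(frame)
        )
        cand = CandidateModel("mu", "nonlinear", tuple(reference.NONLINEAR_MU))
        theta, names, rss_fast = fit_nonlinear_fast(cand, frame, y)
        m = ExponentialTrendModel(cand).fit(frame, y)
        assert rss_fast == pytest.approx(m.rss_, rel=1e-6)
        assert np.allclose(theta, m.coef_, atol=1e-4)


class TestPredict:
    def test_england_linear_mu_worked_value(self, england_models):
        frame = make_frame([1], [40], [2003])
        mu = england_models["mu_linear"].predict(frame)[0]
        assert mu == pytest.approx(3.2920, abs=5e-4)
        assert np.exp(mu) == pytest.approx(26.9, abs=0.1)

    def test_england_nonlinear_mu_algebraic_check(self, england_models):
        # sex=0, age=0 isolates a - b at the centring year
        frame = make_frame([0], [0], [2003])
        val = england_models["mu_nonlinear"].predict(frame)[0]
        assert val == pytest.approx(
            reference.NONLINEAR_MU["a"] - reference.NONLINEAR_MU["b"], abs=1e-9
        )

    def test_zero_coefficients_predict_zero(self):
        cand = CandidateModel("mu", "linear", ("intercept", "sex", "age", "year"))
        frame = _random_frame(20, with_mu=False)
        m = LinearTrendModel(cand)
        m.term_names_ = list(cand.terms)
        m.coef_ = np.zeros(4)
        assert np.all(m.predict(frame) == 0.0)

    def test_prediction_linear_in_coefficients(self):
        cand = CandidateModel("mu", "linear", ("intercept", "sex", "age", "year"))
        frame = _random_frame(30, with_mu=False)
        m = LinearTrendModel(cand)
        m.term_names_ = list(cand.terms)
        t1, t2 = np.array([1.0, 0.5, 0.01, 0.002]), np.array([0.3, -0.2, 0.03, -0.001])
        m.coef_ = 2.0 * t1 + 3.0 * t2
        combined = m.predict(frame)
        m.coef_ = t1
        p1 = m.predict(frame)
        m.coef_ = t2
        p2 = m.predict(frame)
        assert np.allclose(combined, 2.0 * p1 + 3.0 * p2)


class TestFitStats:
    def test_perfect_fit(self):
        frame = _random_frame(60, with_mu=False)
        y = 0.5 + 0.1 * frame["sex"].to_numpy() + 0.01 * frame["age"].to_numpy()
        cand = CandidateModel("mu", "linear", ("intercept", "sex", "age", "year"))
        st = fit_stats(LinearTrendModel(cand).fit(frame, y))
        assert st["r_squared"] == pytest.approx(1.0)
        assert st["deviance"] == pytest.approx(0.0, abs=1e-20)

    def test_aic_bic_internal_consistency(self, cohort_frame):
        cand = CandidateModel("mu", "linear", ("intercept", "sex", "age", "year", "age2", "year2"))
        st = fit_stats(fit_linear(cand, cohort_frame))
        k, n, ll = 6, st["n_obs"], st["loglik"]
        assert st["aic"] == pytest.approx(2 * k - 2 * ll, abs=1e-6)
        assert st["bic"] == pytest.approx(k * np.log(n) - 2 * ll, abs=1e-6)

    def test_residual_df_arithmetic(self):
        frame = _random_frame(400, seed=11, with_mu=False)
        rng = np.random.default_rng(11)
        y = evaluate_surface(reference.LINEAR_MU, frame) + rng.normal(0, 0.01, 400)
        cand = CandidateModel(
            "mu", "linear", tuple(reference.LINEAR_MU) + ("sex:age",)
        )
        st = fit_stats(LinearTrendModel(cand).fit(frame, y))
        assert st["df_model"] == 6  # slope terms; 7 parameters with the intercept
        assert st["df_resid"] == 393

    def test_nonlinear_reports_no_r_squared(self, cohort_frame):
        cand = CandidateModel("mu", "nonlinear", ("a", "b", "c", "sex", "age", "age2"))
        st = fit_stats(fit_nonlinear(cand, cohort_frame))
        assert st["r_squared"] is None
        assert st["df_resid"] == st["n_obs"] - 6


class TestSerialisation:
    def test_roundtrip_preserves_predictions(self, cohort_frame):
        cand = CandidateModel("mu", "linear", ("intercept", "sex", "age", "year", "age2", "year2"))
        m = fit_linear(cand, cohort_frame)
        m2 = model_from_dict(model_to_dict(m))
        frame = make_frame([1, 0], [40, 70], [2020, 2035])
        assert np.allclose(m.predict(frame), m2.predict(frame))
        assert np.allclose(m.cov_, m2.cov_)
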