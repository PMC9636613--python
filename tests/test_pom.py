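import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression

from ordiscore import (
    GeneratorSpec,
    OrdinalData,
    PredictorSpec,
    ProportionalOddsModel,
    fit_pom,
    gen_cohort,
    pom_loglik,
)


def _cat_cohort(y, **cols):
    df = pd.DataFrame({**cols, "outcome": y})
    return OrdinalData(df, "outcome", categorical=tuple(cols))


class TestLoglik:
    def test_symmetric_binary_no_predictors(self):
        d = _cat_cohort([1, 2])
        assert pom_loglik([0.0], {}, d) == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_three_category_closed_form(self):
        # theta = (0, logit 0.8): P(Y=2) = 0.8 - 0.5 = 0.3
        d = _cat_cohort([2])
        ll = pom_loglik([0.0, np.log(0.8 / 0.2)], {}, d)
        assert ll == pytest.approx(np.log(0.3), abs=1e-10)

    def test_matches_fit_loglik(self, binary_cohort):
        fit = fit_pom(binary_cohort)
        assert fit.converged
        assert pom_loglik(fit.theta, fit.coef, binary_cohort) == pytest.approx(
            fit.loglik, abs=1e-6
        )

    def test_rejects_non_monotone_theta(self):
        with pytest.raises(ValueError):
            pom_loglik([1.0, 0.0], {}, _cat_cohort([1, 2, 3]))


class TestFit:
    def test_intercept_only_closed_form(self):
        y = np.repeat([1, 2, 3], [5, 3, 2])
        d = OrdinalData(pd.DataFrame({"outcome": y}), "outcome", predictors=())
        fit = fit_pom(d)
        assert fit.theta == pytest.approx([0.0, np.log(0.8 / 0.2)], abs=1e-10)

    def test_binary_outcome_matches_logistic_regression(self):
        rng = np.random.default_rng(10)
        n = 4000
        x = rng.integers(0, 2, n)
        p = 1 / (1 + np.exp(-(-0.5 + 1.2 * x)))
        y = 1 + rng.binomial(1, p)
        d = _cat_cohort(y, x=x)
        fit = fit_pom(d)
        lr = LogisticRegression(C=np.inf, tol=1e-10, max_iter=1000)
        lr.fit(x[:, None], y)
        # logit P(Y=2) = -theta_1 + beta x
        assert fit.coef["x"]["1"] == pytest.approx(lr.coef_[0][0], abs=1e-5)
        assert -fit.theta[0] == pytest.approx(lr.intercept_[0], abs=1e-5)

    def test_loglik_matches_grid_oracle_tiny_data(self):
        # n = 6, one binary predictor, J = 2: free params (theta_1, beta)
        d = _cat_cohort([1, 2, 1, 2, 2, 1], x=[0, 0, 1, 1, 0, 1])
        fit = fit_pom(d)

        def nll(p):
            return -pom_loglik([p[0]], {"x": {"0": 0.0, "1": p[1]}}, d)

        best = min(
            (
                minimize(nll, [t0, b0], method="Nelder-Mead").fun
                for t0, b0 in itertools.product([-1, 0, 1], repeat=2)
            )
        )
        assert fit.loglik == pytest.approx(-best, abs=1e-4)

    def test_parameter_recovery_within_3se(self, three_binary_spec):
        from dataclasses import replace

        data = gen_cohort(replace(three_binary_spec, n=50000, seed=77))
        fit = fit_pom(data)
        assert fit.converged
        # SE of a POM coefficient at this n is well under 0.05
        for i, name in enumerate(("x1", "x2", "x3"), start=1):
            assert fit.coef[name]["1"] == pytest.approx(0.4 * i, abs=3 * 0.05)
        assert fit.theta == pytest.approx([0.2, 1.5], abs=0.1)

    def test_bias_shrinks_with_n(self, three_binary_spec):
        from dataclasses import replace

        errs = []
        for n in (1000, 10000, 100000):
            data = gen_cohort(replace(three_binary_spec, n=n, seed=123))
            fit = fit_pom(data)
            errs.append(abs(fit.coef["x3"]["1"] - 1.2))
        assert errs[2] < errs[0]

    def test_separation_reported_not_raised(self):
        # x perfectly predicts the outcome -> infinite MLE
        d = _cat_cohort([1] * 20 + [3] * 20, x=[0] * 20 + [1] * 20)
        fit = fit_pom(d)
        assert isinstance(fit.converged, bool)  # no crash; flag carries the state


class TestPredict:
    def test_no_predictors_half(self):
        d = OrdinalData(pd.DataFrame({"outcome": [1, 2, 1, 2]}), "outcome", predictors=())
        fit = fit_pom(d)
        cum = fit.predict_cumprob(pd.DataFrame(index=[0]))
        assert cum[0, 0] == pytest.approx(0.5, abs=1e-10)

    def test_category_probs_closed_form(self):
        y = np.repeat([1, 2, 3], [5, 3, 2])
        d = OrdinalData(pd.DataFrame({"outcome": y}), "outcome", predictors=())
        fit = fit_pom(d)
        probs = fit.predict_catprob(pd.DataFrame(index=[0]))
        assert probs[0] == pytest.approx([0.5, 0.3, 0.2], abs=1e-10)

    def test_cumprobs_increasing_and_catprobs_sum_to_one(self, binary_cohort):
        fit = fit_pom(binary_cohort)
        sample = binary_cohort.df.head(50)
        cum = fit.predict_cumprob(sample)
        assert np.all(np.diff(cum, axis=1) > 0)
        cat = fit.predict_catprob(sample)
        assert np.all(cat >= 0)
        assert np.allclose(cat.sum(axis=1), 1.0, atol=1e-12)

    def test_positive_coefficient_lowers_cumprob(self, binary_cohort):
        fit = fit_pom(binary_cohort)
        lo = fit.predict_cumprob(pd.DataFrame([{"x1": 0, "x2": 0, "x3": 0}]))
        hi = fit.predict_cumprob(pd.DataFrame([{"x1": 0, "x2": 0, "x3": 1}]))
        assert np.all(hi < lo)  # higher risk level => lower P(Y <= j)

    def test_unseen_level_errors_unless_coerced(self, binary_cohort):
        fit = fit_pom(binary_cohort)
        rec = pd.DataFrame([{"x1": 7, "x2": 0, "x3": 0}])
        with pytest.raises(KeyError):
            fit.predict_catprob(rec)
        base = pd.DataFrame([{"x1": 0, "x2": 0, "x3": 0}])
        assert np.allclose(
            fit.predict_catprob(rec, coerce=True), fit.predict_catprob(base)
        )


class TestRelevel:
    @pytest.fixture()
    def mixed_sign_fit(self):
        spec = GeneratorSpec(
            n=6000,
            theta=(-0.5, 1.0),
            predictors=(
                PredictorSpec("a", "bernoulli", {"p": 0.5}, coef=0.8),
                PredictorSpec(
                    "c",
                    "categorical",
                    {"levels": ["lo", "mid", "hi"], "probs": [0.3, 0.4, 0.3]},
                    coef={"lo": 0.0, "mid": -0.4, "hi": 0.6},
                ),
            ),
            seed=21,
        )
        return fit_pom(gen_cohort(spec))

    def test_relevel_makes_all_coefficients_nonnegative(self, mixed_sign_fit):
        rel = mixed_sign_fit.relevel_positive()
        for var, cmap in rel.coef.items():
            vals = np.array(list(cmap.values()))
            assert np.all(vals >= 0)
            assert cmap[rel.references[var]] == 0.0
        # 'mid' has the smallest coefficient -> becomes the reference
        assert rel.references["c"] == "mid"

    def test_relevel_preserves_loglik_and_predictions(self, mixed_sign_fit):
        rel = mixed_sign_fit.relevel_positive()
        assert rel.loglik == pytest.approx(mixed_sign_fit.loglik, abs=1e-8)
        rng = np.random.default_rng(0)
        recs = pd.DataFrame(
            {
                "a": rng.integers(0, 2, 100),
                "c": rng.choice(["lo", "mid", "hi"], 100),
            }
        )
        np.testing.assert_allclose(
            rel.predict_catprob(recs), mixed_sign_fit.predict_catprob(recs), atol=1e-8
        )

    def test_shift_and_refit_routes_agree(self, mixed_sign_fit):
        shift = mixed_sign_fit.relevel_positive(method="shift")
        refit = mixed_sign_fit.relevel_positive(method="refit")
        assert shift.loglik == pytest.approx(refit.loglik, abs=1e-6)
        for var in shift.coef:
            for lvl in shift.coef[var]:
                assert shift.coef[var][lvl] == pytest.approx(refit.coef[var][lvl], abs=1e-4)

    def test_already_positive_is_idempotent(self, binary_cohort):
        fit = fit_pom(binary_cohort).relevel_positive()
        again = fit.relevel_positive()
        assert again.loglik == pytest.approx(fit.loglik, abs=1e-10)
        for var in fit.coef:
            assert again.coef[var] == pytest.approx(fit.coef[var], abs=1e-10)

    def test_non_converged_rejected(self, binary_cohort):
        fit = fit_pom(binary_cohort)
        fit.converged = False
        with pytest.raises(ValueError):
            fit.relevel_positive()


def test_continuous_predictor_rejected():
    df = pd.DataFrame({"x": [0.5, 1.5, 2.5, 3.0], "outcome": [1, 2, 1, 2]})
    with pytest.raises(ValueError, match="continuous"):
        ProportionalOddsModel(OrdinalData(df, "outcome"))
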