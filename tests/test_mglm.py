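import numpy as np
import pandas as pd
import pytest

from otterdiet.mglm import (
    DesignError, DietCompositionModel, build_design, fit_binomial_cloglog,
    irls_cloglog, manyglm_fit, stepwise_aic,
)


def simulate_binary(rng, n, beta, link="cloglog"):
    """One response column from a cloglog model with given coefficients."""
    x = rng.normal(size=n)
    eta = beta[0] + beta[1] * x
    p = -np.expm1(-np.exp(eta))
    return x, (rng.random(n) < p).astype(float)


@pytest.fixture
def small_fit_data():
    rng = np.random.default_rng(10)
    x, y = simulate_binary(rng, 80, (-0.5, 0.8))
    X = np.column_stack([np.ones(80), x])
    return X, y


class TestCloglogFit:
    def test_intercept_only_closed_form(self):
        y = np.array([0, 1, 1, 0, 1, 0, 1, 1, 0, 1], float)
        fit = fit_binomial_cloglog(y, np.ones((10, 1)))
        pbar = y.mean()
        assert fit.params.iloc[0] == pytest.approx(np.log(-np.log(1 - pbar)),
                                                   abs=1e-8)

    def test_constant_response_flagged_nonconvergent(self):
        with pytest.warns(UserWarning, match="converge"):
            fit = fit_binomial_cloglog(np.ones(20), np.ones((20, 1)))
        assert not fit.converged

    def test_deviance_matches_statsmodels(self, small_fit_data):
        sm = pytest.importorskip("statsmodels.api")
        X, y = small_fit_data
        fit = fit_binomial_cloglog(y, X)
        ref = sm.GLM(
            y, X, family=sm.families.Binomial(sm.families.links.CLogLog())
        ).fit()
        assert fit.deviance == pytest.approx(ref.deviance, abs=1e-6)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-5)

    def test_deviance_matches_direct_likelihood_optimizer(self, small_fit_data):
        from scipy.optimize import minimize

        X, y = small_fit_data

        def nll(beta):
            eta = np.clip(X @ beta, -30, 3.2)
            p = np.clip(-np.expm1(-np.exp(eta)), 1e-10, 1 - 1e-10)
            return -(y * np.log(p) + (1 - y) * np.log1p(-p)).sum()

        opt = minimize(nll, np.zeros(X.shape[1]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        fit = fit_binomial_cloglog(y, X)
        assert fit.deviance == pytest.approx(2 * opt.fun, abs=1e-6)

    def test_aic_definition(self, small_fit_data):
        X, y = small_fit_data
        fit = fit_binomial_cloglog(y, X)
        assert fit.aic == pytest.approx(fit.deviance + 2 * X.shape[1])

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(DesignError):
            fit_binomial_cloglog(np.zeros(20), X)


class TestBatchedIrls:
    def test_batch_equals_column_by_column(self):
        rng = np.random.default_rng(11)
        n, G = 40, 5
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Y = (rng.random((n, G)) < 0.4).astype(float)
        beta_b, dev_b, _, _ = irls_cloglog(X, Y)
        for g in range(G):
            # extra refinement iterations in the batch shift estimates ~1e-6
            beta_s, dev_s, _, _ = irls_cloglog(X, Y[:, g])
            np.testing.assert_allclose(beta_b[:, g], beta_s[:, 0], atol=1e-5)
            assert dev_b[g] == pytest.approx(dev_s[0], abs=1e-7)

    def test_identical_columns_identical_fits(self):
        rng = np.random.default_rng(12)
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 0.5).astype(float)
        Y = np.column_stack([y, y])
        beta, dev, _, _ = irls_cloglog(X, Y)
        np.testing.assert_array_equal(beta[:, 0], beta[:, 1])
        assert dev[0] == dev[1]


class TestDesign:
    def test_treatment_coding_lexical_reference(self):
        cov = pd.DataFrame({"habitat": ["main", "lake", "tributary", "lake"]})
        X, names, _ = build_design(cov, ["habitat"])
        assert names == ["Intercept", "habitat[T.main]", "habitat[T.tributary]"]
        np.testing.assert_array_equal(X[:, 1], [1, 0, 0, 0])

    def test_interaction_columns(self):
        cov = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 4.0, 5.0], "sex": ["F", "M", "M", "F", "M"]}
        )
        X, names, term_cols = build_design(cov, ["x", "sex", "x:sex"])
        assert "x:sex[T.M]" in names
        j = names.index("x:sex[T.M]")
        np.testing.assert_array_equal(X[:, j], [0.0, 2.0, 3.0, 0.0, 5.0])
        assert term_cols["x:sex"] == [j]

    def test_aliased_columns_named(self):
        cov = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        with pytest.raises(DesignError, match="aliased"):
            build_design(cov, ["a", "b"])

    def test_missing_rows_dropped_with_count(self):
        resp = pd.DataFrame({"g": [1, 0, 1]}, index=["a", "b", "c"])
        cov = pd.DataFrame({"x": [1.0, np.nan, 3.0]}, index=["a", "b", "c"])
        model = DietCompositionModel(resp, cov, ["x"])
        assert model.n_dropped == 1
        assert len(model.response) == 2


@pytest.fixture(scope="module")
def fitted_model():
    rng = np.random.default_rng(13)
    n, G = 120, 6
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    etas = -0.8 + np.outer(x, np.linspace(0, 1.2, G))
    P = -np.expm1(-np.exp(etas))
    Y = pd.DataFrame(
        (rng.random((n, G)) < P).astype(int),
        columns=[f"g{i}" for i in range(G)],
    )
    cov = pd.DataFrame({"x": x, "z": z})
    model = DietCompositionModel(Y, cov, ["x", "z"])
    return model, model.fit()


class TestManyGlm:
    def test_community_deviance_is_sum_of_groups(self, fitted_model):
        _, res = fitted_model
        assert res.community_deviance == pytest.approx(res.deviances.sum())

    def test_multivariate_aic_is_sum(self, fitted_model):
        _, res = fitted_model
        assert res.aic == pytest.approx(res.group_aic.sum())

    def test_nesting_monotonicity_per_group(self, fitted_model):
        model, res = fitted_model
        sub = DietCompositionModel(model.response, model.covariates, ["x"])
        res_sub = sub.fit()
        assert (res.deviances <= res_sub.deviances + 1e-8).all()

    def test_manyglm_fit_wrapper(self, fitted_model):
        model, res = fitted_model
        res2 = manyglm_fit(model.response, model.covariates, ["x", "z"])
        pd.testing.assert_frame_equal(res.params, res2.params)

    def test_summary_renders(self, fitted_model):
        _, res = fitted_model
        text = res.summary()
        assert "cloglog" in text
        assert "g0" in text


class TestLrTest:
    def test_statistic_additivity_and_p_range(self, fitted_model):
        _, res = fitted_model
        t = res.lr_test("x", n_resamples=99, seed=5)
        assert t.community_deviance == pytest.approx(t.group_deviance.sum())
        assert 0 < t.p_value <= 1
        assert ((t.group_p_adjusted > 0) & (t.group_p_adjusted <= 1)).all()

    def test_seed_determinism_bit_for_bit(self, fitted_model):
        _, res = fitted_model
        t1 = res.lr_test("x", n_resamples=99, seed=42)
        t2 = res.lr_test("x", n_resamples=99, seed=42)
        assert t1.p_value == t2.p_value
        pd.testing.assert_series_equal(t1.group_p_adjusted, t2.group_p_adjusted)

    def test_null_term_not_significant_strong_term_is(self, fitted_model):
        _, res = fitted_model
        tx = res.lr_test("x", n_resamples=199, seed=1)
        tz = res.lr_test("z", n_resamples=199, seed=2)
        assert tx.p_value <= 0.05  # slope up to 1.2 across six groups
        assert tz.p_value > 0.05

    def test_adjusted_p_dominates_unadjusted_ordering(self, fitted_model):
        # step-down adjustment is monotone in the observed statistics
        _, res = fitted_model
        t = res.lr_test("x", n_resamples=99, seed=3)
        d = t.group_deviance.sort_values(ascending=False)
        p = t.group_p_adjusted[d.index]
        assert (np.diff(p.to_numpy()) >= -1e-12).all()

    def test_coarse_resampling_warns(self, fitted_model):
        _, res = fitted_model
        with pytest.warns(UserWarning, match="coarse"):
            res.lr_test("x", n_resamples=49, seed=1)


class TestAnova:
    def test_single_term_table_matches_lr_test(self):
        rng = np.random.default_rng(14)
        n = 100
        x, _ = simulate_binary(rng, n, (-0.5, 0.0))
        Y = pd.DataFrame({"g0": (rng.random(n) < 0.3).astype(int),
                          "g1": (rng.random(n) < 0.5).astype(int)})
        cov = pd.DataFrame({"x": x})
        res = DietCompositionModel(Y, cov, ["x"]).fit()
        table = res.anova(n_resamples=99, seed=7)
        row = table.table.iloc[0]
        # same statistic as a direct test of the only term
        direct = res.lr_test("x", n_resamples=99, seed=0)
        assert row["deviance"] == pytest.approx(direct.community_deviance)

    def test_sequential_terms_listed_in_order(self, fitted_model):
        _, res = fitted_model
        table = res.anova(terms=["x", "z"], n_resamples=99, seed=9)
        assert list(table.table["term"]) == ["x", "z"]
        gt = table.group_table()
        assert set(gt["term"]) == {"x", "z"}


class TestStepwise:
    def test_strong_effect_retained(self):
        rng = np.random.default_rng(15)
        n = 200
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        eta = -0.6 + 2.0 * x
        p = -np.expm1(-np.exp(eta))
        Y = pd.DataFrame({"g0": (rng.random(n) < p).astype(int),
                          "g1": (rng.random(n) < p).astype(int)})
        cov = pd.DataFrame({"x": x, "noise": noise})
        selected = stepwise_aic(Y, cov, ["x", "noise"])
        assert "x" in selected

    def test_pure_noise_mostly_gives_empty_model(self):
        rng = np.random.default_rng(16)
        n = 250
        wins = 0
        for _ in range(20):
            cov = pd.DataFrame({"u": rng.normal(size=n),
                                "v": rng.normal(size=n)})
            Y = pd.DataFrame({"g0": (rng.random(n) < 0.4).astype(int),
                              "g1": (rng.random(n) < 0.3).astype(int)})
            if stepwise_aic(Y, cov, ["u", "v"]) == []:
                wins += 1
        assert wins >= 11

    def test_interaction_requires_main_effects(self):
        rng = np.random.default_rng(17)
        n = 150
        cov = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        Y = pd.DataFrame({"g0": (rng.random(n) < 0.4).astype(int)})
        selected = stepwise_aic(Y, cov, ["a", "b", "a:b"])
        if "a:b" in selected:
            assert {"a", "b"} <= set(selected)
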