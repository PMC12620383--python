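"""Robust regression engine: OLS/logit fits, VIFs, effect sizes, grids."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from conftest import small_config, wide_outcome

from peermod.config import CohortConfig, default_outcome_specs
from peermod.moderation import (
    IDX_INT,
    ExposureStore,
    ModelSpec,
    RankDeficiencyError,
    SeparationError,
    build_design,
    build_model_specs,
    fit_model,
    interaction_delta_r2,
    logit_fit_robust,
    mean_center,
    ols_fit_hc,
    standardized_interaction,
    vif,
)
from peermod.synthetic import generate_cohort


class TestMeanCenter:
    def test_simple_example(self):
        np.testing.assert_allclose(mean_center([1, 2, 3]), [-1, 0, 1])

    def test_constant_vector_to_zeros(self):
        np.testing.assert_allclose(mean_center([4.0, 4.0]), [0.0, 0.0])

    def test_idempotent(self):
        v = np.random.default_rng(0).normal(size=20)
        np.testing.assert_allclose(mean_center(mean_center(v)), mean_center(v))

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            mean_center([np.nan, np.nan])


class TestOlsSandwich:
    def test_exact_linear_data_zero_robust_se(self):
        x = np.arange(10.0)
        X = np.column_stack([np.ones(10), x])
        y = 2 + 3 * x
        fit = ols_fit_hc(X, y)
        np.testing.assert_allclose(fit.params, [2, 3], atol=1e-10)
        np.testing.assert_allclose(fit.se, 0, atol=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_six_point_bivariate_matches_hand_sandwich(self):
        X = np.column_stack([np.ones(6), [0, 1, 2, 3, 4, 5.0]])
        y = np.array([1.0, 2.5, 2.0, 4.5, 4.0, 7.0])
        bread = np.linalg.inv(X.T @ X)
        beta = bread @ X.T @ y
        e = y - X @ beta
        cov = 6 / 4 * bread @ (X.T @ np.diag(e**2) @ X) @ bread
        fit = ols_fit_hc(X, y, "HC1")
        np.testing.assert_allclose(fit.params, beta, atol=1e-10)
        np.testing.assert_allclose(fit.se, np.sqrt(np.diag(cov)), atol=1e-10)

    @pytest.mark.parametrize("variant", ["HC0", "HC1", "HC3"])
    def test_matches_statsmodels(self, variant):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n, k = int(rng.integers(20, 50)), int(rng.integers(2, 6))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
            y = rng.normal(size=n)
            fit = ols_fit_hc(X, y, variant)
            ref = sm.OLS(y, X).fit(cov_type=variant, use_t=True)
            np.testing.assert_allclose(fit.params, ref.params, atol=1e-10)
            np.testing.assert_allclose(fit.se, ref.bse, atol=1e-10)
            np.testing.assert_allclose(fit.pvalues, ref.pvalues, atol=1e-10)

    def test_homoskedastic_hc1_close_to_classical(self):
        """Under homoskedasticity the mean HC1 SE tracks the classical SE."""
        rng = np.random.default_rng(2)
        ratios = []
        for _ in range(1000):
            n = 60
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = X @ [1, 0.5, -0.5] + rng.normal(size=n)
            fit = ols_fit_hc(X, y, "HC1")
            classical = sm.OLS(y, X).fit()
            ratios.append(fit.se[1] / classical.bse[1])
        assert abs(np.mean(ratios) - 1) < 0.03

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0)])
        with pytest.raises(RankDeficiencyError, match="x"):
            ols_fit_hc(X, np.random.default_rng(3).normal(size=20))


class TestLogitRobust:
    def test_balanced_null_gives_zero_intercept(self):
        X = np.ones((40, 1))
        y = np.array([0.0, 1.0] * 20)
        fit = logit_fit_robust(X, y)
        assert fit.params[0] == pytest.approx(0.0, abs=1e-10)

    def test_two_by_two_equals_log_odds_ratio(self):
        # exposure x: 45/90 vs 30/80 events
        x = np.repeat([0.0, 1.0], [80, 90])
        y = np.concatenate([np.repeat([0, 1.0], [50, 30]), np.repeat([0, 1.0], [45, 45])])
        X = np.column_stack([np.ones_like(x), x])
        fit = logit_fit_robust(X, y)
        log_or = np.log((45 / 45) / (30 / 50))
        assert fit.params[1] == pytest.approx(log_or, abs=1e-8)

    def test_recovers_known_dgp(self):
        rng = np.random.default_rng(4)
        n = 5000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        truth = np.array([-0.5, 0.8])
        p = 1 / (1 + np.exp(-X @ truth))
        y = (rng.random(n) < p).astype(float)
        fit = logit_fit_robust(X, y)
        np.testing.assert_allclose(fit.params, truth, atol=4 * fit.se.max())

    def test_perfect_separation_detected(self):
        x = np.concatenate([-np.ones(10), np.ones(10)])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            logit_fit_robust(np.column_stack([np.ones(20), x]), y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logit_fit_robust(np.ones((10, 1)), np.ones(10))


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        X = np.column_stack(
            [np.ones(n), np.tile([1, -1.0], 32), np.repeat([1, -1.0], 32)]
        )
        scores = vif(X, ("const", "a", "b"))
        assert scores["a"] == pytest.approx(1.0, abs=1e-10)
        assert scores["b"] == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_column_infinite(self):
        z = np.random.default_rng(5).normal(size=30)
        X = np.column_stack([np.ones(30), z, z])
        scores = vif(X, ("const", "a", "b"))
        assert np.isinf(scores["a"]) and np.isinf(scores["b"])

    def test_known_correlation_closed_form(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=2000)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.normal(size=2000)
        X = np.column_stack([np.ones(2000), a, b])
        r = np.corrcoef(a, b)[0, 1]
        scores = vif(X, ("const", "a", "b"))
        assert scores["a"] == pytest.approx(1 / (1 - r**2), abs=1e-8)


class TestEffectSizes:
    def test_standardized_interaction_arithmetic(self):
        x = np.array([0.0, 2.0])  # sd = sqrt(2)
        y = np.array([0.0, 4.0])  # sd = 2*sqrt(2)
        assert standardized_interaction(0.3, x, y) == pytest.approx(0.15)

    def test_equal_sds_leave_coefficient_unchanged(self):
        v = np.random.default_rng(7).normal(size=50)
        assert standardized_interaction(0.42, v, v) == pytest.approx(0.42)

    def test_outcome_rescaling_halves_beta_std(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert standardized_interaction(1.0, x, 2 * y) == pytest.approx(
            standardized_interaction(1.0, x, y) / 2
        )

    def test_delta_r2_zero_interaction_large_n(self):
        rng = np.random.default_rng(9)
        n = 20000
        X = np.column_stack(
            [np.ones(n), rng.normal(size=n), rng.normal(size=n)]
        )
        X = np.column_stack([X[:, 0], X[:, 1], X[:, 2], X[:, 1] * X[:, 2]])
        y = X[:, 1] + 0.5 * X[:, 2] + rng.normal(size=n)
        assert interaction_delta_r2(X, y) < 5e-4

    def test_delta_r2_equals_squared_semipartial_when_orthogonalized(self):
        rng = np.random.default_rng(10)
        n = 500
        base = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        prod_raw = base[:, 1] * base[:, 2]
        # orthogonalize the product against the other columns
        coeffs, *_ = np.linalg.lstsq(base, prod_raw, rcond=None)
        prod = prod_raw - base @ coeffs
        X = np.column_stack([base, prod])
        y = rng.normal(size=n) + 0.3 * prod
        delta = interaction_delta_r2(X, y)
        r_semi = np.corrcoef(prod, y)[0, 1]
        assert delta == pytest.approx(r_semi**2, abs=1e-10)


@pytest.fixture(scope="module")
def fitted_store():
    cohort, noms = generate_cohort(small_config(), seed=21)
    return cohort, ExposureStore(cohort, noms)


class TestDesignAndGrid:
    def test_dichotomous_moderator_product_column(self, fitted_store):
        cohort, store = fitted_store
        spec = ModelSpec("y1", "linear", "class", 0, "setting")
        X, y, names, meta = build_design(spec, cohort, store)
        i_mod, i_int, i_peer = names.index("moderator"), names.index("interaction"), names.index("peer_exposure")
        w = X[:, i_mod]
        assert set(np.unique(w)) <= {0.0, 1.0}
        np.testing.assert_allclose(X[:, i_int], X[:, i_peer] * w)
        assert meta["moderator_kind"] == "dichotomous"

    def test_no_missing_data_preserves_rows(self):
        cohort, noms = generate_cohort(
            small_config(missing_rate=0.0, nomination_mean_outdegree=8.0), seed=22
        )
        store = ExposureStore(cohort, noms)
        spec = ModelSpec("y1", "linear", "year", 0, "pro_sociality")
        X, y, *_ = build_design(spec, cohort, store)
        assert len(y) == len(cohort)

    def test_one_missing_moderator_drops_one_row(self, fitted_store):
        cohort, store = fitted_store
        cohort2 = cohort.copy()
        full_mask = cohort2.y1_w1.notna()
        target = cohort2.index[full_mask][0]
        cohort2.loc[target, "pro_sociality"] = np.nan
        store2 = ExposureStore(cohort2, store.nominations)
        spec = ModelSpec("y1", "linear", "year", 0, "pro_sociality")
        _, y_ref, *_ = build_design(spec, cohort, store)
        _, y_new, *_ = build_design(spec, cohort2, store2)
        assert len(y_new) == len(y_ref) - 1

    def test_product_formed_after_centering(self, fitted_store):
        cohort, store = fitted_store
        spec = ModelSpec("y2", "linear", "friends", 0, "pro_sociality")
        X, _, names, _ = build_design(spec, cohort, store)
        i_p, i_m, i_i = (names.index(c) for c in ("peer_exposure", "moderator", "interaction"))
        assert abs(X[:, i_p].mean()) < 1e-10
        assert abs(X[:, i_m].mean()) < 1e-10
        np.testing.assert_allclose(X[:, i_i], X[:, i_p] * X[:, i_m])

    def test_interaction_p_invariant_to_moderator_rescaling(self, fitted_store):
        cohort, store = fitted_store
        spec = ModelSpec("y1", "linear", "friends", 0, "pro_sociality")
        f1 = fit_model(spec, cohort, store)
        cohort2 = cohort.copy()
        cohort2["pro_sociality"] = 3.0 * cohort2["pro_sociality"] - 11.0
        f2 = fit_model(spec, cohort2, ExposureStore(cohort2, store.nominations))
        assert f1.interaction_p == pytest.approx(f2.interaction_p, abs=1e-10)

    def test_grid_cardinalities(self):
        outcomes = [s.name for s in default_outcome_specs()]
        binary = {"susceptibility"}
        assert len(build_model_specs("setting", outcomes, binary)) == 276
        assert len(build_model_specs("se_emotional", outcomes, binary)) == 258
        total_se = sum(
            len(build_model_specs(m, outcomes, binary))
            for m in ("se_emotional", "se_friends", "se_opportunity")
        )
        assert total_se == 774
        friends_only = build_model_specs(
            "school_ses", outcomes, binary, peer_groups=("friends",)
        )
        assert len(friends_only) == 92

    def test_logistic_outcome_fits(self, ):
        cfg = small_config(
            n_schools=4,
            outcome_specs=(
                wide_outcome("y1"),
                CohortConfig().outcome_specs[-1],  # susceptibility spec
            ),
        )
        cohort, noms = generate_cohort(cfg, seed=23)
        store = ExposureStore(cohort, noms, {"susceptibility"})
        fit = fit_model(
            ModelSpec("susceptibility", "logistic", "class", 0, "pro_sociality"),
            cohort, store,
        )
        assert fit.ok
        assert 0 <= fit.interaction_p <= 1
        assert fit.beta_std is None

    def test_unfit_models_recorded_not_raised(self, fitted_store):
        cohort, store = fitted_store
        fit = fit_model(
            ModelSpec("y1", "linear", "friends", 0, "nonexistent_moderator"),
            cohort, store,
        )
        assert not fit.ok
        assert "nonexistent" in fit.reason
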