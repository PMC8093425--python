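"""Mixed-model meta-regression: scaling, AICc, selection, bootstrap, R2."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from precipdiv.inference import (
    ModelSpec,
    aicc,
    back_transform,
    bootstrap_ci,
    candidate_set,
    conditional_r2,
    direction_interaction_test,
    fit_lmm,
    fit_marginal_lmm,
    prepare_effects,
    quadratic_test,
    select_model,
    standardize_covariates,
)
from precipdiv.synthetic_data import generate_effectsize_table


@pytest.fixture()
def sim_table(rng):
    tab, truth = generate_effectsize_table(
        [0.05, 0.2, -0.1, -0.15], (0.1, 0.1, 0.1, 0.2), 20, 3, 5, rng
    )
    return tab, truth


@pytest.fixture()
def sim_df(sim_table):
    df, _ = prepare_effects(sim_table[0], "S", "local", standardize=False)
    return df


class TestStandardize:
    def test_scaled_mean_zero_sd_half(self, rng):
        df = pd.DataFrame({"x": rng.normal(10, 3, 200), "y": rng.normal(size=200)})
        out, scaling = standardize_covariates(df, ["x"])
        assert out["x_s"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x_s"].std(ddof=1) == pytest.approx(0.5)

    def test_binary_symmetric(self):
        df = pd.DataFrame({"x": [0.0, 1.0] * 10})
        out, _ = standardize_covariates(df, ["x"])
        vals = sorted(out["x_s"].unique())
        assert vals[0] == pytest.approx(-vals[1])

    def test_back_transform_inverts(self, rng):
        df = pd.DataFrame({"x": rng.normal(5, 2, 50)})
        out, scaling = standardize_covariates(df, ["x"])
        np.testing.assert_allclose(back_transform(out["x_s"], "x", scaling), df["x"])

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_covariates(pd.DataFrame({"x": [1.0] * 5}), ["x"])


class TestAICc:
    def test_direct_arithmetic(self):
        # -2(-10) + 2*3 + 2*3*4/(20-3-1) = 26 + 1.5
        assert aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_correction_vanishes_with_n(self, rng):
        for _ in range(20):
            ll = rng.normal(-50, 10)
            k = int(rng.integers(1, 8))
            aic = -2 * ll + 2 * k
            assert aicc(ll, k, 10**6) == pytest.approx(aic, abs=1e-3)
            n = int(rng.integers(k + 2, 100))
            expected = aic + 2 * k * (k + 1) / (n - k - 1)
            assert aicc(ll, k, n) == pytest.approx(expected)

    def test_undefined_for_tiny_n(self):
        assert aicc(-10.0, 5, 6) == np.inf


class TestCandidateSet:
    def test_default_ladder(self):
        specs = candidate_set()
        names = [s.name for s in specs]
        assert names[0] == "1"
        assert names[1] == "delta_P_s"
        assert len(specs) == 5
        assert all(s.satisfies_marginality() for s in specs)

    def test_pet_substitution(self):
        specs = candidate_set(climate="PET")
        assert any("PET_s" in s.name for s in specs)
        assert not any("MAP_s" in s.name for s in specs)

    def test_robustness_variants_satisfy_marginality(self):
        specs = candidate_set(quadratic=True, direction_interaction=True)
        assert any("I(delta_P_s ** 2)" in s.name for s in specs)
        assert any("direction" in s.name for s in specs)
        assert all(s.satisfies_marginality() for s in specs)


class TestFitLMM:
    def test_matches_ols_oracle_without_random_variance(self, rng):
        """Zero random-effect variance: fixed effects agree with plain OLS."""
        tab, _ = generate_effectsize_table([0.1, 0.3], (0, 0, 0, 0.3), 15, 3, 4, rng)
        df, _ = prepare_effects(tab, "S", "local", standardize=False)
        spec = ModelSpec(fixed_terms=("delta_P_s",), scale="local")
        fit = fit_lmm(df, spec)
        ols = sm.OLS(df["lrr"], sm.add_constant(df["delta_P_s"])).fit()
        assert fit.coefficients["delta_P_s"] == pytest.approx(
            ols.params["delta_P_s"], abs=2 * ols.bse["delta_P_s"]
        )

    def test_intercept_only_is_grand_mean_on_balanced_data(self, rng):
        tab, _ = generate_effectsize_table([0.2], (0, 0, 0, 0.1), 10, 2, 3, rng)
        df, _ = prepare_effects(tab, "S", "local", standardize=False)
        fit = fit_lmm(df, ModelSpec(fixed_terms=(), scale="local"))
        assert fit.coefficients["Intercept"] == pytest.approx(df["lrr"].mean(), abs=1e-4)

    def test_row_order_invariance(self, sim_df):
        spec = ModelSpec(fixed_terms=("delta_P_s", "MAP_s"), scale="local")
        a = fit_lmm(sim_df, spec)
        shuffled = sim_df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b = fit_lmm(shuffled, spec)
        for k in a.coefficients:
            assert a.coefficients[k] == pytest.approx(b.coefficients[k], abs=1e-6)

    def test_aicc_exceeds_aic_and_k_counts(self, sim_df):
        spec = ModelSpec(fixed_terms=("delta_P_s",), scale="local")
        fit = fit_lmm(sim_df, spec)
        assert fit.aicc >= fit.aic
        # every fixed effect, every variance component and the residual
        assert fit.k_params == len(fit.coefficients) + len(fit.variance_components) + 1

    def test_parameter_recovery_single(self, sim_table):
        tab, truth = sim_table
        df, _ = prepare_effects(tab, "S", "local", standardize=False)
        spec = ModelSpec(
            fixed_terms=("delta_P_s", "MAP_s", "delta_P_s:MAP_s"), scale="local"
        )
        fit = fit_lmm(df, spec, reml=True)
        for name, true_val in truth["coefficients"].items():
            est = fit.coefficients[name]
            se = fit.coef_se[name]
            assert abs(est - true_val) < 3 * se, (name, est, true_val, se)


class TestConditionalR2:
    def test_equals_marginal_without_random_variance(self, rng):
        tab, _ = generate_effectsize_table([0.0, 0.5], (0, 0, 0, 0.2), 15, 3, 4, rng)
        df, _ = prepare_effects(tab, "S", "local", standardize=False)
        fit = fit_lmm(df, ModelSpec(fixed_terms=("delta_P_s",), scale="local"))
        assert fit.conditional_r2 == pytest.approx(fit.marginal_r2, abs=0.02)

    def test_near_one_for_near_perfect_fit(self, rng):
        tab, _ = generate_effectsize_table([0.0, 0.5], (0, 0, 0, 1e-4), 10, 3, 4, rng)
        df, _ = prepare_effects(tab, "S", "local", standardize=False)
        fit = fit_lmm(df, ModelSpec(fixed_terms=("delta_P_s",), scale="local"))
        assert fit.conditional_r2 > 0.999

    def test_variance_partition_oracle(self, sim_df):
        spec = ModelSpec(fixed_terms=("delta_P_s", "MAP_s"), scale="local")
        fit = fit_lmm(sim_df, spec)
        X = fit.result.model.exog
        var_f = np.var(X @ np.asarray(fit.result.fe_params))
        var_re = sum(fit.variance_components.values())
        tot = var_f + var_re + fit.residual_variance
        m, c = conditional_r2(fit)
        assert m == pytest.approx(var_f / tot, abs=1e-6)
        assert c == pytest.approx((var_f + var_re) / tot, abs=1e-6)
        assert 0 <= m <= c <= 1


class TestSelection:
    def test_strong_slope_selected(self, rng):
        tab, _ = generate_effectsize_table([0.0, 0.6], (0.05, 0.05, 0.05, 0.1), 20, 3, 4, rng)
        df, _ = prepare_effects(tab, "S", "local", standardize=False)
        rank, best = select_model(df, candidate_set(scale="local"))
        assert "delta_P_s" in best.spec.fixed_terms
        assert rank["delta_aicc"].iloc[0] == 0.0

    def test_best_fit_uses_reml_and_ml_aicc(self, sim_df):
        rank, best = select_model(sim_df, candidate_set(scale="local"))
        assert best.method == "REML"
        assert np.isfinite(best.aicc)


class TestBootstrap:
    def test_seed_reproducible(self, sim_df):
        spec = ModelSpec(fixed_terms=("delta_P_s",), scale="local")
        ci1, d1 = bootstrap_ci(sim_df, spec, n_iter=25, rng=np.random.default_rng(9))
        ci2, d2 = bootstrap_ci(sim_df, spec, n_iter=25, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(d1, d2)
        assert ci1 == ci2

    def test_ci_narrow_for_near_zero_noise(self, rng):
        tab, _ = generate_effectsize_table([0.0, 0.4], (0, 0, 0, 1e-3), 10, 3, 4, rng)
        df, _ = prepare_effects(tab, "S", "local", standardize=False)
        spec = ModelSpec(fixed_terms=("delta_P_s",), scale="local")
        ci, _ = bootstrap_ci(df, spec, n_iter=40, rng=rng)
        lo, hi = ci["delta_P_s"]
        assert hi - lo < 0.01
        assert lo <= 0.4 <= hi


class TestRobustnessTests:
    def test_quadratic_report_structure(self, sim_df):
        rep = quadratic_test(sim_df, ModelSpec(fixed_terms=("delta_P_s",), scale="local"))
        assert rep["winner"] in ("base", "extended")
        assert rep["delta_aicc"] >= 0

    def test_quadratic_requires_linear_term(self, sim_df):
        with pytest.raises(ValueError):
            quadratic_test(sim_df, ModelSpec(fixed_terms=(), scale="local"))

    def test_direction_equal_slopes_null(self, rng):
        tab, _ = generate_effectsize_table([0.0, 0.3], (0.05, 0.05, 0.05, 0.15), 25, 3, 4, rng)
        df, _ = prepare_effects(tab, "S", "local", standardize=False)
        rep = direction_interaction_test(
            df, ModelSpec(fixed_terms=("delta_P_s",), scale="local")
        )
        assert abs(rep["slope_difference"]) < 2 * rep["slope_difference_se"]
        assert rep["slope_increase"] == pytest.approx(
            rep["fit_extended"].coefficients["delta_P_s"] + rep["slope_difference"]
        )

    def test_direction_needs_both_groups(self, sim_df):
        one_sided = sim_df[sim_df["direction"] == "increase"]
        with pytest.raises(ValueError):
            direction_interaction_test(
                one_sided, ModelSpec(fixed_terms=("delta_P_s",), scale="local")
            )


class TestMarginalFitter:
    def test_matches_mixedlm_with_equal_weights(self, rng):
        tab, _ = generate_effectsize_table([0.1, 0.25], (0.1, 0.1, 0.1, 0.2), 12, 2, 4, rng)
        df, _ = prepare_effects(tab, "S", "local", standardize=False)
        spec = ModelSpec(fixed_terms=("delta_P_s",), scale="local")
        ref = fit_lmm(df, spec, reml=True)
        X = np.column_stack([np.ones(len(df)), df["delta_P_s"]])
        groups = [df["study_id"].to_numpy(), df["site_uid"].to_numpy(), df["block_uid"].to_numpy()]
        beta, variances, llf, ok = fit_marginal_lmm(
            df["lrr"].to_numpy(), X, groups, reml=True
        )
        assert ok
        assert beta[0] == pytest.approx(ref.coefficients["Intercept"], abs=1e-3)
        assert beta[1] == pytest.approx(ref.coefficients["delta_P_s"], abs=1e-3)

    def test_rejects_nonpositive_weights(self, rng):
        y = rng.normal(size=10)
        X = np.ones((10, 1))
        with pytest.raises(ValueError):
            fit_marginal_lmm(y, X, [np.repeat([0, 1], 5)], weights=np.zeros(10))
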