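import numpy as np
import pytest
from scipy import optimize
from scipy.special import expit, logit

from meadowsem.bivariate import (
    bivariate_table,
    deviance_residual_normality,
    estimate_boxcox_lambda,
    fit_fractional_logit,
    fit_linear_aic,
    spearman_rho,
)


def quasi_loglik(beta, y, X):
    """Independent oracle: the Bernoulli quasi-log-likelihood."""
    mu = expit(X @ beta)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


class TestFractionalLogit:
    def test_constant_half_intercept_only(self):
        y = np.full(10, 0.5)
        X = np.empty((10, 0))
        fit = fit_fractional_logit(y, X, add_intercept=True)
        assert fit.params[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.fitted == pytest.approx(0.5)

    def test_two_group_closed_form(self):
        # saturated two-group model: slope = logit(p1) - logit(p0)
        g = np.repeat([0, 1], 8)
        y = np.where(g == 0, 0.25, 0.7)
        fit = fit_fractional_logit(y, g.astype(float))
        assert fit.params[0] == pytest.approx(logit(0.25), abs=1e-6)
        assert fit.params[1] == pytest.approx(logit(0.7) - logit(0.25), abs=1e-6)

    def test_oracle_equivalence_20_rows(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20), rng.normal(size=20)])
        y = rng.uniform(0.05, 0.95, size=20)
        fit = fit_fractional_logit(y, X[:, 1:], add_intercept=True)
        res = optimize.minimize(
            lambda b: -quasi_loglik(b, y, X),
            np.zeros(3),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        assert fit.params == pytest.approx(res.x, abs=1e-5)

    def test_binary_response_matches_logistic_mle(self, rng):
        x = rng.normal(size=30)
        y = (rng.random(30) < expit(0.5 + x)).astype(float)
        fit = fit_fractional_logit(y, x)
        X = np.column_stack([np.ones(30), x])
        res = optimize.minimize(
            lambda b: -quasi_loglik(b, y, X), np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        assert fit.params == pytest.approx(res.x, abs=1e-5)

    def test_out_of_range_response_rejected(self):
        with pytest.raises(ValueError):
            fit_fractional_logit(np.array([0.5, 1.2]), np.array([1.0, 2.0]))

    def test_rank_deficient_rejected(self):
        y = np.full(6, 0.4)
        X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="rank"):
            fit_fractional_logit(y, X)

    def test_perfect_separation_flagged_not_raised(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        y = (x > 0).astype(float)
        fit = fit_fractional_logit(y, x)
        assert not fit.converged
        assert fit.diagnostic != ""

    def test_predictions_in_unit_interval_and_residual_count(self, rng):
        x = rng.normal(size=15)
        y = rng.uniform(0, 1, size=15)
        fit = fit_fractional_logit(y, x)
        assert np.all((fit.fitted > 0) & (fit.fitted < 1))
        assert len(fit.deviance_residuals) == 15


class TestLinearAIC:
    def test_exact_line(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        fit = fit_linear_aic(y, x, allow_quadratic=True)
        assert fit.degree == 1
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.params == pytest.approx([1.0, 2.0], abs=1e-8)

    def test_exact_parabola_prefers_quadratic(self):
        x = np.linspace(-3, 3, 12)
        y = 1 + 0.5 * x + 2 * x**2
        fit = fit_linear_aic(y, x, allow_quadratic=True)
        assert fit.degree == 2
        assert fit.aic_by_degree[2] < fit.aic_by_degree[1]

    def test_boxcox_lambda_near_zero_for_exponential(self, rng):
        x = np.linspace(0.5, 3.0, 40)
        y = np.exp(x) * np.exp(rng.normal(0, 0.01, size=40))
        fit = fit_linear_aic(y, x, allow_quadratic=False, box_cox=True)
        assert abs(fit.box_cox_lambda) < 0.1
        # grid-search oracle at step 0.01 on the same profile likelihood
        from meadowsem.bivariate import boxcox_profile_loglik

        X = np.column_stack([np.ones_like(x), x])
        grid = np.arange(-2.0, 2.0, 0.01)
        lls = [boxcox_profile_loglik(y, X, l) for l in grid]
        lam_grid = grid[int(np.argmax(lls))]
        assert fit.box_cox_lambda == pytest.approx(lam_grid, abs=0.01)

    def test_boxcox_requires_positive(self):
        with pytest.raises(ValueError):
            fit_linear_aic(np.array([1.0, -1.0, 2.0, 3.0]), np.arange(4.0), box_cox=True)

    def test_min_observations(self):
        with pytest.raises(ValueError):
            fit_linear_aic(np.ones(3), np.arange(3.0))

    def test_aic_selection_invariant_to_affine_x(self, rng):
        x = rng.normal(size=25)
        y = 0.3 * x + rng.normal(0, 0.5, size=25)
        f1 = fit_linear_aic(y, x)
        f2 = fit_linear_aic(y, 5.0 * x - 2.0)
        assert f1.degree == f2.degree
        assert f1.aic == pytest.approx(f2.aic, abs=1e-8)

    def test_boxcox_lambda_one_is_unit_shift(self, rng):
        x = np.linspace(0, 1, 20)
        y = 3 + 2 * x + rng.normal(0, 0.1, 20)
        from meadowsem.bivariate import boxcox_transform

        assert boxcox_transform(y, 1.0) == pytest.approx(y - 1.0)


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [9, 7, 5, 3]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks of a = (1,2,3,4), ranks of b = (2,1,4,3):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 6*4/60 = 0.6
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_input_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = spearman_rho([1, 1, 1], [1, 2, 3])
        assert np.isnan(out)

    def test_length_checks(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2])


class TestResidualNormality:
    def test_seeded_normal_sample_not_rejected(self):
        resid = np.random.default_rng(1234).standard_normal(200)
        out = deviance_residual_normality(resid)
        assert out.pvalue > 0.05
        assert not out.degenerate

    def test_constant_residuals_degenerate(self):
        out = deviance_residual_normality(np.zeros(20))
        assert out.degenerate

    def test_smoke_on_synthetic_fit(self, default_dataset, rng):
        _, my, _ = default_dataset
        g = my.groupby("meadow")
        fit = fit_fractional_logit(
            g["occupancy_rate"].mean().to_numpy(), g["mean_score"].first().to_numpy()
        )
        out = deviance_residual_normality(fit)
        assert np.isfinite(out.skewness) and np.isfinite(out.kurtosis)


class TestDirectionality:
    def test_signs_match_expected_gradients(self):
        # large simulations: occupancy-rate slope positive, utilization
        # and quality slopes negative, in nearly all replicates
        from meadowsem.synthetic import StudyDesign, TrueParams, simulate

        design = StudyDesign(
            n_allotments=10, meadows_per_allotment=(10,) * 10,
            sites_per_meadow=3, years=(2007,),
        )
        good = 0
        n_rep = 10
        for rep in range(n_rep):
            _, my, _ = simulate(design, TrueParams(), seed=500 + rep)
            g = my.groupby("meadow")
            w = g["mean_score"].first().to_numpy()
            occ = fit_fractional_logit(g["occupancy_rate"].mean().to_numpy(), w)
            util = fit_linear_aic(
                g["utilization_mid"].mean().to_numpy(), w, allow_quadratic=False
            )
            cp = fit_linear_aic(g["cp_mid"].mean().to_numpy(), w, allow_quadratic=False)
            if occ.params[1] > 0 and util.params[1] < 0 and cp.params[1] < 0:
                good += 1
        assert good >= int(0.95 * n_rep)


def test_bivariate_table_smoke(default_dataset):
    _, my, _ = default_dataset
    table = bivariate_table(my)
    assert {"model", "term", "estimate", "se", "p"} <= set(table.columns)
    assert (table.groupby("model").size() >= 2).all()
    occ = table[(table.model == "occ_rate~wetness") & (table.term == "wetness")]
    assert occ["estimate"].item() > 0
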