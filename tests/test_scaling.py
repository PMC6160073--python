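"""Power-law and logit-link fits, correlation statistics, one-way ANOVA."""

import math

import numpy as np
import pytest

from gudscale.scaling import (
    fit_logit_fraction,
    fit_power_law,
    pearson_with_ci,
    residual_charge_anova,
)


def _ols_oracle(x, y):
    """Normal-equations OLS of y on x: returns (intercept, slope)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[0], beta[1]


class TestPowerLaw:
    def test_noiseless_power_law_recovered_exactly(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        fit = fit_power_law(x, 2.0 * x**0.5)
        assert fit.intercept == pytest.approx(2.0, rel=1e-12)
        assert fit.slope == pytest.approx(0.5, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope_ci95 == pytest.approx(0.0, abs=1e-9)

    def test_constant_y_gives_zero_slope(self):
        fit = fit_power_law([1.0, 2.0, 4.0, 8.0], [3.0] * 4)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.3, 4.0])  # one point perturbed
        b0, b1 = _ols_oracle(np.log(x), np.log(y))
        fit = fit_power_law(x, y)
        assert fit.slope == pytest.approx(b1, abs=1e-12)
        assert fit.intercept == pytest.approx(math.exp(b0), rel=1e-12)

    def test_slope_invariant_to_rescaling_x(self):
        x = np.array([1.0, 3.0, 7.0, 20.0])
        y = np.array([2.0, 5.0, 9.0, 30.0])
        base = fit_power_law(x, y)
        scaled = fit_power_law(10.0 * x, y)
        assert scaled.slope == pytest.approx(base.slope, rel=1e-12)
        assert scaled.intercept == pytest.approx(base.intercept * 10.0**-base.slope, rel=1e-9)

    def test_rejects_nonpositive_values_naming_rows(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            fit_power_law([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="n >= 3"):
            fit_power_law([1.0, 2.0], [1.0, 2.0])

    def test_ci_coverage_on_lognormal_noise(self):
        """The t-based 95% slope CI covers the generating exponent ~95% of the time."""
        rng = np.random.default_rng(42)
        beta, n_rep, n = 0.8, 1000, 12
        x = np.geomspace(0.5, 50, n)
        covered = 0
        for _ in range(n_rep):
            y = 1.7 * x**beta * rng.lognormal(0.0, 0.3, size=n)
            fit = fit_power_law(x, y)
            covered += abs(fit.slope - beta) <= fit.slope_ci95
        assert 0.93 <= covered / n_rep <= 0.97

    def test_pearson_r_is_signed_root_of_r_squared(self):
        rng = np.random.default_rng(3)
        x = np.geomspace(1, 30, 10)
        y = 2.0 * x**-0.4 * rng.lognormal(0, 0.2, 10)
        fit = fit_power_law(x, y)
        assert abs(fit.r_pearson) == pytest.approx(math.sqrt(fit.r_squared), rel=1e-12)
        assert fit.r_pearson < 0


class TestLogitFraction:
    def test_constant_fraction_uninformative(self):
        fit = fit_logit_fraction([1.0, 2.0, 4.0, 8.0], [0.3] * 4)
        assert fit.slope == pytest.approx(0.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_logistic_recovered(self):
        x = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        y = 1.0 / (1.0 + np.exp(-(0.5 + 2.0 * np.log(x))))
        fit = fit_logit_fraction(x, y)
        assert fit.slope == pytest.approx(2.0, rel=1e-6)
        assert fit.intercept == pytest.approx(0.5, rel=1e-6)
        assert 0.0 <= fit.r_squared <= 1.0

    def test_pseudo_r2_matches_likelihood_oracle(self):
        """McFadden ratio against an independent numerical MLE of the
        Bernoulli-form logit model."""
        from scipy.optimize import minimize

        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0, 13.0, 21.0, 34.0])
        y = np.array([0.10, 0.15, 0.12, 0.30, 0.35, 0.50, 0.55, 0.70])
        lx = np.log(x)

        def nll(params):
            mu = 1.0 / (1.0 + np.exp(-(params[0] + params[1] * lx)))
            return -np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))

        opt = minimize(nll, [0.0, 0.0], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        ll_fit = -opt.fun
        ll_null = np.sum(y * np.log(y.mean()) + (1 - y) * np.log(1 - y.mean()))
        oracle = 1.0 - ll_fit / ll_null
        fit = fit_logit_fraction(x, y)
        assert fit.r_squared == pytest.approx(oracle, rel=1e-5)
        assert fit.slope == pytest.approx(opt.x[1], rel=1e-4)
        assert 0.0 <= fit.r_squared <= 1.0

    def test_rejects_out_of_range_fractions(self):
        with pytest.raises(ValueError):
            fit_logit_fraction([1.0, 2.0, 3.0], [0.2, 1.4, 0.5])

    def test_boundary_values_nudged(self):
        fit = fit_logit_fraction([1.0, 2.0, 4.0, 8.0], [0.0, 0.2, 0.6, 1.0])
        assert np.isfinite(fit.slope) and fit.slope > 0


class TestPearson:
    def test_exact_line(self):
        res = pearson_with_ci([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_orthogonal_vectors(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert pearson_with_ci(x, y).r == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.0, 1.0, 5.0, 6.0, 9.0])
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson_with_ci(x, y).r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = pearson_with_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate and math.isnan(res.r)

    def test_ci_contains_r(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.0, 1.0, 5.0, 6.0, 9.0])
        res = pearson_with_ci(x, y)
        assert res.ci_low <= res.r <= res.ci_high


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = residual_charge_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.f_statistic == pytest.approx(0.0)

    def test_hand_computed_example(self):
        res = residual_charge_anova([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        assert res.f_statistic == pytest.approx(1.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            residual_charge_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            residual_charge_anova([[1.0, 2.0], [3.0]])
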