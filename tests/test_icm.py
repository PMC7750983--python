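"""RMA regression, prediction algebra, Gibbs posterior, and HPDs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from molarcascade.data import MolarRowSizes, compute_ratios
from molarcascade.icm import (
    PosteriorDraws,
    _sample_invwishart,
    adjust_for_measurement_error,
    density_mode,
    evaluate_predictions,
    fit_posterior,
    hpd_interval,
    prediction_one_fit,
    rma_regression,
    theoretical_covariance_structure,
    theoretical_m3_ratio,
)
from molarcascade.synthetic import GeneratorConfig, simulate_rows


def _rows_from_array(arr):
    df = pd.DataFrame(np.asarray(arr, float), columns=["m1", "m2", "m3"])
    df.insert(0, "specimen_id", [f"S{i}" for i in range(len(df))])
    return MolarRowSizes(df)


class TestRMARegression:
    def test_exact_icm_line_recovered(self):
        x = np.linspace(0.7, 0.95, 25)
        y = 2 * x - 1
        fit = rma_regression(x, y, n_resamples=200, seed=0)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(-1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_slope_and_intercept(self):
        # independent closed-form oracle: slope = sign(corr)*sd(y)/sd(x),
        # intercept through the means
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 2.0, 3.0])
        fit = rma_regression(x, y, n_resamples=100, seed=1)
        slope_expected = np.std(y, ddof=1) / np.std(x, ddof=1)
        assert fit.slope == pytest.approx(slope_expected, rel=1e-12)
        assert fit.slope == pytest.approx(1.52753, abs=1e-5)
        assert fit.intercept == pytest.approx(
            y.mean() - slope_expected * x.mean(), rel=1e-12
        )

    def test_negative_correlation_gives_negative_slope(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = -1.5 * x + rng.normal(scale=0.1, size=40)
        fit = rma_regression(x, y, n_resamples=200, seed=2)
        assert fit.slope < 0

    def test_axis_swap_slopes_multiply_to_one(self, default_ratios):
        x = default_ratios.ratio("r21")
        y = default_ratios.ratio("r31")
        a = rma_regression(x, y, n_resamples=50, seed=0).slope
        b = rma_regression(y, x, n_resamples=50, seed=0).slope
        assert a * b == pytest.approx(1.0, rel=1e-10)

    def test_ci_brackets_point_estimate(self, default_ratios):
        fit = rma_regression(
            default_ratios.ratio("r21"),
            default_ratios.ratio("r31"),
            n_resamples=500,
            seed=4,
        )
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]
        assert fit.intercept_ci[0] <= fit.intercept <= fit.intercept_ci[1]

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            rma_regression([1, 1, 1], [1, 2, 3])

    def test_association_p_small_on_strong_signal(self, default_ratios):
        fit = rma_regression(
            default_ratios.ratio("r21"),
            default_ratios.ratio("r31"),
            n_resamples=100,
            seed=5,
        )
        assert fit.p_value <= 0.01


class TestPredictionOneFit:
    def test_exact_line_r2_one_p_at_floor(self):
        x = np.linspace(0.6, 1.0, 30)
        r2, p = prediction_one_fit(x, 2 * x - 1, n_permutations=999, seed=0)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(1 / 1000)

    def test_duplicated_dataset_keeps_r2(self, default_ratios):
        x = default_ratios.ratio("r21")
        y = default_ratios.ratio("r31")
        r2_single, _ = prediction_one_fit(x, y, n_permutations=99, seed=1)
        r2_double, _ = prediction_one_fit(
            np.r_[x, x], np.r_[y, y], n_permutations=99, seed=1
        )
        assert r2_double == pytest.approx(r2_single, rel=1e-12)

    def test_type_one_error_calibrated_on_independent_data(self):
        # independent x, y: permutation p should be ~uniform
        rng = np.random.default_rng(12)
        rejections = 0
        n_seeds = 200
        for s in range(n_seeds):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            _, p = prediction_one_fit(x, y, n_permutations=199, seed=s)
            rejections += p <= 0.05
        assert 0.01 < rejections / n_seeds < 0.10


class TestPredictionAlgebra:
    @pytest.mark.parametrize(
        "mu_r21, expected", [(1.0, 1.0), (0.8, 0.6), (0.5, 0.0), (0.75, 0.5)]
    )
    def test_mean_rule(self, mu_r21, expected):
        assert theoretical_m3_ratio(mu_r21) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "block, expected",
        [((1.0, 1.0, 0.5), (3.0, 0.0, 1.5)), ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0))],
    )
    def test_covariance_rule_worked_values(self, block, expected):
        assert theoretical_covariance_structure(*block) == pytest.approx(expected)

    def test_covariance_rule_matches_brute_force_sample_covariance(self):
        # oracle: build M3 := 2*M2 - M1 and compare against np.cov directly
        rng = np.random.default_rng(77)
        for _ in range(5):
            m1 = rng.normal(10, 1, size=500)
            m2 = 0.8 * m1 + rng.normal(0, 0.5, size=500)
            m3 = 2 * m2 - m1
            cov = np.cov(np.c_[m1, m2, m3], rowvar=False)
            var3, cov13, cov23 = theoretical_covariance_structure(
                cov[0, 0], cov[1, 1], cov[0, 1]
            )
            assert var3 == pytest.approx(cov[2, 2], rel=1e-9)
            assert cov13 == pytest.approx(cov[0, 2], rel=1e-9)
            assert cov23 == pytest.approx(cov[1, 2], rel=1e-9)

    def test_invalid_covariance_block_rejected(self):
        with pytest.raises(ValueError):
            theoretical_covariance_structure(1.0, 1.0, 1.5)


class TestInvWishartSampler:
    def test_moments_match_scipy_invwishart(self):
        # mean of IW(df, S) is S/(df - p - 1); check against scipy's pdf
        # parameterization via its own mean
        df, scale = 12.0, np.array([[2.0, 0.3, 0.0], [0.3, 1.0, 0.1], [0.0, 0.1, 0.5]])
        rng = np.random.default_rng(8)
        draws = np.array([_sample_invwishart(rng, df, scale) for _ in range(4000)])
        expected = stats.invwishart(df=df, scale=scale).mean()
        np.testing.assert_allclose(draws.mean(axis=0), expected, rtol=0.1, atol=0.02)


class TestFitPosterior:
    def test_recovers_known_covariance(self):
        # replicated over independent datasets: a single data draw can
        # legitimately sit >3 posterior SDs from the generating matrix,
        # so the bound is required for the majority of datasets
        cov = np.array(
            [[0.04, 0.02, 0.01], [0.02, 0.05, 0.015], [0.01, 0.015, 0.03]]
        )
        hits = 0
        for s in range(5):
            cfg = GeneratorConfig(
                seed=31 + s,
                mode="mvn",
                n_specimens=500,
                mean_vector=(5.0, 4.0, 3.0),
                covariance_matrix=tuple(map(tuple, cov)),
                groups=(),
            )
            rows = simulate_rows(cfg)
            draws = fit_posterior(rows, n_draws=1000, burn_in=500, thin=2, seed=1)
            post_mean = draws.sigma.mean(axis=0)
            post_sd = draws.sigma.std(axis=0)
            hits += bool(np.all(np.abs(post_mean - cov) <= 3 * post_sd))
        assert hits >= 4

    def test_posterior_mean_sigma_tracks_sample_covariance(self, default_rows):
        # the conjugate structure pins E[Sigma | data] near the sample
        # covariance; this isolates sampler bias from data-draw noise
        draws = fit_posterior(default_rows, n_draws=1000, burn_in=500, thin=2, seed=6)
        sample_cov = np.cov(default_rows.sizes, rowvar=False)
        np.testing.assert_allclose(
            draws.sigma.mean(axis=0), sample_cov, rtol=0.08, atol=2e-4
        )

    def test_posterior_mean_mu_matches_sample_mean(self, default_rows):
        draws = fit_posterior(default_rows, n_draws=500, burn_in=200, thin=2, seed=2)
        np.testing.assert_allclose(
            draws.mu.mean(axis=0),
            default_rows.sizes.mean(axis=0),
            rtol=5e-3,
        )

    def test_constant_column_raises_singularity_error(self):
        arr = np.column_stack(
            [np.full(20, 1.5), np.linspace(1.0, 1.4, 20), np.linspace(0.7, 1.1, 20)]
        )
        with pytest.raises(np.linalg.LinAlgError, match="zero sample variance"):
            fit_posterior(_rows_from_array(arr))

    def test_too_few_rows_rejected(self):
        arr = np.array([[1.5, 1.2, 0.9], [1.6, 1.3, 1.0], [1.4, 1.1, 0.8]])
        with pytest.raises(ValueError, match="at least 4"):
            fit_posterior(_rows_from_array(arr))

    def test_reproducible_from_seed(self, default_rows):
        a = fit_posterior(default_rows, n_draws=50, burn_in=50, thin=1, seed=9)
        b = fit_posterior(default_rows, n_draws=50, burn_in=50, thin=1, seed=9)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_sigma_draws_positive_definite(self, default_rows):
        draws = fit_posterior(default_rows, n_draws=200, burn_in=100, thin=1, seed=3)
        eig = np.linalg.eigvalsh(draws.sigma)
        assert np.all(eig > 0)

    def test_effective_sample_size_near_nominal(self, default_rows):
        # conjugate two-block Gibbs should have negligible autocorrelation
        draws = fit_posterior(default_rows, n_draws=500, burn_in=200, thin=1, seed=4)
        for i, j in ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)):
            x = draws.sigma[:, i, j]
            x = x - x.mean()
            rho1 = np.dot(x[:-1], x[1:]) / np.dot(x, x)
            ess = len(x) * (1 - rho1) / (1 + rho1)
            assert ess >= 200


class TestMeasurementErrorAdjustment:
    def test_identity_at_repeatability_one(self, default_rows):
        draws = fit_posterior(default_rows, n_draws=50, burn_in=50, thin=1, seed=5)
        adj = adjust_for_measurement_error(draws, 1.0)
        np.testing.assert_array_equal(adj.sigma, draws.sigma)
        np.testing.assert_array_equal(adj.mu, draws.mu)

    def test_variances_scaled_covariances_untouched(self, default_rows):
        draws = fit_posterior(default_rows, n_draws=50, burn_in=50, thin=1, seed=5)
        adj = adjust_for_measurement_error(draws, 0.5)
        np.testing.assert_allclose(
            np.diagonal(adj.sigma, axis1=1, axis2=2),
            0.5 * np.diagonal(draws.sigma, axis1=1, axis2=2),
        )
        assert np.array_equal(adj.sigma[:, 0, 1], draws.sigma[:, 0, 1])
        np.testing.assert_array_equal(adj.mu, draws.mu)

    def test_composition_multiplies(self, default_rows):
        draws = fit_posterior(default_rows, n_draws=50, burn_in=50, thin=1, seed=5)
        twice = adjust_for_measurement_error(
            adjust_for_measurement_error(draws, 0.9), 0.8
        )
        once = adjust_for_measurement_error(draws, 0.72)
        np.testing.assert_allclose(twice.sigma, once.sigma)
        assert twice.repeatability == pytest.approx(0.72)

    def test_out_of_range_repeatability_rejected(self, default_rows):
        draws = fit_posterior(default_rows, n_draws=50, burn_in=50, thin=1, seed=5)
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                adjust_for_measurement_error(draws, bad)


class TestHPDInterval:
    def test_point_mass(self):
        lo, hi = hpd_interval(np.full(100, 3.2), 0.95)
        assert (lo, hi) == (3.2, 3.2)

    def test_uniform_width_matches_analytic(self):
        rng = np.random.default_rng(21)
        lo, hi = hpd_interval(rng.uniform(0, 1, size=100_000), 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_normal_quantiles_recovered(self):
        rng = np.random.default_rng(22)
        lo, hi = hpd_interval(rng.standard_normal(100_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(5), 0.95)

    def test_shortest_interval_on_skewed_sample(self):
        # exponential: HPD hugs zero, unlike the equal-tailed interval
        rng = np.random.default_rng(23)
        x = rng.exponential(size=50_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo < 0.01
        assert hi < np.quantile(x, 0.975)


class TestEvaluatePredictions:
    def test_icm_exact_data_consistent_on_all_six(self, icm_exact_rows):
        draws = fit_posterior(
            icm_exact_rows, n_draws=1000, burn_in=500, thin=2, seed=6
        )
        report = evaluate_predictions(draws)
        assert report.n_consistent == 6

    def test_independent_m3_breaks_covariance_predictions(self):
        rng = np.random.default_rng(41)
        m1 = rng.normal(1.55, 0.08, size=300)
        m2 = 0.8 * m1 + rng.normal(0, 0.03, size=300)
        m3 = rng.normal(1.0, 0.05, size=300)  # decoupled from M1, M2
        draws = fit_posterior(
            _rows_from_array(np.c_[m1, m2, m3]),
            n_draws=800,
            burn_in=500,
            thin=2,
            seed=7,
        )
        report = evaluate_predictions(draws)
        broken = [
            name
            for name in ("var_m3", "cov_m1_m3", "cov_m2_m3")
            if not report.table[name]["consistent"]
        ]
        assert len(broken) >= 2

    def test_unstable_parameter_flagged_not_consistent(self):
        # theoretical cov(M1,M3) = 2*cov12 - var1 ~ 0 when corr12 is weak
        rng = np.random.default_rng(55)
        m1 = rng.normal(1.55, 0.08, size=300)
        m2 = 0.8 * m1 * 0 + rng.normal(1.24, 0.064, size=300)  # independent
        m3 = 2 * m2 - m1
        draws = fit_posterior(
            _rows_from_array(np.c_[m1, m2, m3]),
            n_draws=500,
            burn_in=300,
            thin=2,
            seed=8,
        )
        report = evaluate_predictions(draws)
        row = report.table["cov_m1_m3"]
        assert not row["stable"]
        assert not row["consistent"]
        assert report.n_consistent <= 5

    def test_mode_lies_inside_hpd_for_stable_parameters(self, icm_exact_rows):
        draws = fit_posterior(
            icm_exact_rows, n_draws=500, burn_in=300, thin=2, seed=9
        )
        report = evaluate_predictions(draws)
        for row in report.table.values():
            if row["stable"]:
                assert row["hpd_low"] <= row["mode"] <= row["hpd_high"]


class TestDensityMode:
    def test_mode_of_gaussian_sample_near_mean(self):
        rng = np.random.default_rng(61)
        x = rng.normal(2.0, 0.5, size=20_000)
        assert density_mode(x) == pytest.approx(2.0, abs=0.05)
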