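import numpy as np
import pytest

from lrtrend import CohortConfig, fit_course, fit_feature_trend, simulate_cohort, zscore_normalize
from lrtrend.errors import DegenerateDesignError, ValidationError


def ols_oracle(x, y):
    """Independent normal-equations solve."""
    A = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
    return slope, intercept


class TestFitFeatureTrend:
    def test_exact_line(self):
        x = np.arange(1, 6)
        fit = fit_feature_trend(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.err == pytest.approx(0.0, abs=1e-12)
        assert fit.lrtf == pytest.approx(3.0, abs=1e-12)

    def test_constant_series(self):
        fit = fit_feature_trend([1, 2, 3, 4], [7.0] * 4)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(7.0)
        assert fit.lrtf == pytest.approx(7.0)

    def test_matches_normal_equations_on_random_series(self, rng):
        for _ in range(100):
            n = rng.integers(3, 30)
            x = np.sort(rng.choice(np.arange(1, 40), size=n, replace=False)).astype(float)
            y = rng.normal(size=n) * rng.uniform(0.1, 10)
            fit = fit_feature_trend(x, y)
            slope, intercept = ols_oracle(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.lrtf == pytest.approx(slope + intercept, abs=1e-10)
            # OLS residuals sum to zero, which is why a *signed* mean
            # residual cannot serve as a fit error
            resid = y - (fit.slope * x + fit.intercept)
            assert resid.sum() == pytest.approx(0.0, abs=1e-9)
            assert fit.err == pytest.approx(np.abs(resid).mean(), abs=1e-10)

    def test_rmse_error_option(self, rng):
        x = np.arange(1, 11).astype(float)
        y = rng.normal(size=10)
        fit = fit_feature_trend(x, y, err_kind="rmse")
        slope, intercept = ols_oracle(x, y)
        resid = y - (slope * x + intercept)
        assert fit.err == pytest.approx(np.sqrt((resid**2).mean()), abs=1e-10)

    def test_shift_equivariance(self, rng):
        x = np.arange(1, 9).astype(float)
        y = rng.normal(size=8)
        f0 = fit_feature_trend(x, y)
        f1 = fit_feature_trend(x, y + 5.0)
        assert f1.slope == pytest.approx(f0.slope, abs=1e-12)
        assert f1.intercept == pytest.approx(f0.intercept + 5.0, abs=1e-10)
        assert f1.lrtf == pytest.approx(f0.lrtf + 5.0, abs=1e-10)

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            fit_feature_trend([3, 3, 3], [1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            fit_feature_trend([1], [1.0])


class TestFitCourse:
    def test_two_point_fits_are_exact(self, small_cohort):
        table, _ = small_cohort
        course = fit_course(zscore_normalize(table), 2)
        assert np.nanmax(course.err) == pytest.approx(0.0, abs=1e-10)

    def test_zero_noise_recovers_scaled_truth(self, clean_cohort):
        """On noiseless data the fitted z-scale slope equals the true raw
        slope divided by the series sd (the normalization's linear map)."""
        table, truth = clean_cohort
        norm = zscore_normalize(table)
        course = fit_course(norm, table.max_fraction)
        ok = course.valid
        expected = truth.slopes / np.where(norm.sd == 0, 1.0, norm.sd)
        np.testing.assert_allclose(course.slope[ok], expected[ok], atol=1e-8)
        assert np.nanmax(course.err) == pytest.approx(0.0, abs=1e-8)

    def test_course_matches_single_series_fits(self, small_cohort):
        table, _ = small_cohort
        norm = zscore_normalize(table)
        course = fit_course(norm, 7)
        x = norm.fractions[norm.fractions <= 7].astype(float)
        for i in (0, 3):
            for j in (0, 11, 25):
                if not course.valid[i, j]:
                    continue
                y = norm.values[i, norm.fractions <= 7, j]
                single = fit_feature_trend(x[~np.isnan(y)], y[~np.isnan(y)])
                assert course.slope[i, j] == pytest.approx(single.slope, abs=1e-10)
                assert course.err[i, j] == pytest.approx(single.err, abs=1e-10)
                assert course.lrtf[i, j] == pytest.approx(single.lrtf, abs=1e-10)

    def test_slope_error_shrinks_with_more_fractions(self):
        """Averaged over seeds, using more fractions does not worsen slope
        recovery."""
        errs = {n: [] for n in (5, 14, 28)}
        for seed in range(10):
            cfg = CohortConfig(n_patients=6, n_fractions=28, n_features=30,
                              n_informative=10, noise_sd=0.5, seed=100 + seed)
            table, truth = simulate_cohort(cfg)
            norm = zscore_normalize(table)
            sd = np.where(norm.sd == 0, 1.0, norm.sd)
            for n in errs:
                course = fit_course(norm, n)
                err = np.abs(course.slope - truth.slopes / sd)
                errs[n].append(np.nanmean(err[course.valid]))
        means = {n: np.mean(v) for n, v in errs.items()}
        assert means[28] <= means[14] <= means[5]

    def test_slope_rmse_within_analytic_bound(self):
        """Slope-recovery RMSE stays below 3x the analytic OLS slope sd for
        the known design (28 equally spaced fractions, noise sd 0.1)."""
        cfg = CohortConfig(n_patients=8, n_fractions=28, n_features=60,
                           n_informative=0, noise_sd=0.1, effect_slope_sd=0.0,
                           seed=17)
        table, truth = simulate_cohort(cfg)
        # work in raw units: slopes are all 0, so fit the raw cube directly
        cube, _, fractions, _ = table.to_cube()
        x = fractions.astype(float)
        slopes = np.empty(cube.shape[::2])
        for i in range(cube.shape[0]):
            for j in range(cube.shape[2]):
                slopes[i, j] = fit_feature_trend(x, cube[i, :, j]).slope
        analytic_sd = 0.1 / np.sqrt(((x - x.mean()) ** 2).sum())
        rmse = np.sqrt(np.mean((slopes - truth.slopes) ** 2))
        assert rmse < 3 * analytic_sd

    def test_invalid_upto_fraction(self, small_cohort):
        table, _ = small_cohort
        norm = zscore_normalize(table)
        with pytest.raises(ValidationError):
            fit_course(norm, 1)
        with pytest.raises(ValidationError):
            fit_course(norm, 99)

    def test_export_frame(self, small_cohort):
        table, _ = small_cohort
        course = fit_course(zscore_normalize(table), 6)
        df = course.to_frame()
        assert {"patient_id", "feature_id", "n", "slope", "intercept", "err", "lrtf"} \
            <= set(df.columns)
        assert len(df) == int(course.valid.sum())
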