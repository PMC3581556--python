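import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from middomain.inference import (
    CHI2_95_DF2,
    DegenerateFitError,
    EnsembleFit,
    FitResult,
    ellipse_test,
    ensemble_fit,
    regress_obs_on_exp,
)


class TestRegression:
    def test_identity(self):
        x = np.arange(10.0)
        fit = regress_obs_on_exp(x, x)
        assert (fit.r2, fit.intercept, fit.slope) == pytest.approx((1.0, 0.0, 1.0))
        assert fit.n_cells == 10

    def test_affine(self):
        x = np.linspace(0, 5, 20)
        fit = regress_obs_on_exp(2 * x + 3, x)
        assert (fit.r2, fit.intercept, fit.slope) == pytest.approx((1.0, 3.0, 2.0))

    def test_independent_noise_flat(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        fit = regress_obs_on_exp(y, x)
        assert abs(fit.slope) < 0.1
        assert fit.r2 < 0.02

    def test_missing_cells_dropped(self):
        x = np.array([0.0, 1, 2, 3, np.nan])
        y = np.array([0.0, 1, np.nan, 3, 4])
        fit = regress_obs_on_exp(y, x)
        assert fit.n_cells == 3

    def test_too_few_cells_errors(self):
        with pytest.raises(DegenerateFitError):
            regress_obs_on_exp([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_errors(self):
        with pytest.raises(DegenerateFitError):
            regress_obs_on_exp([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_r2_is_squared_pearson_of_fitted(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = 1.5 * x + rng.normal(size=200)
        fit = regress_obs_on_exp(y, x)
        fitted = fit.intercept + fit.slope * x
        assert fit.r2 == pytest.approx(np.corrcoef(y, fitted)[0, 1] ** 2, abs=1e-12)


class TestEnsembleFit:
    def test_identical_tables_all_perfect(self):
        obs = pd.Series(np.arange(10.0))
        tables = [obs.copy() for _ in range(5)]
        ens = ensemble_fit(obs, tables, "richness")
        assert len(ens) == 5
        arr = ens.triples()
        assert np.allclose(arr[:, 0], 1.0) and np.allclose(arr[:, 1], 0.0)
        s = ens.summary()
        assert s["mean_slope"] == pytest.approx(1.0)
        assert s["ci95_intercept"] == [pytest.approx(0.0), pytest.approx(0.0)]

    def test_length_two(self):
        obs = np.arange(5.0)
        ens = ensemble_fit(obs, [obs * 2, obs * 3], "m")
        assert len(ens) == 2

    def test_degenerate_iterations_counted(self):
        obs = np.arange(5.0)
        flat = np.full(5, 2.0)
        ens = ensemble_fit(obs, [obs, flat, obs], "m")
        assert len(ens) == 2 and ens.n_failed == 1

    def test_all_degenerate_errors(self):
        obs = np.arange(5.0)
        with pytest.raises(DegenerateFitError):
            ensemble_fit(obs, [np.full(5, 1.0)], "m")


class TestEllipse:
    def test_tight_cloud_at_target_inside(self):
        rng = np.random.default_rng(0)
        cloud = np.column_stack([rng.normal(0, 1e-3, 100), 1 + rng.normal(0, 1e-3, 100)])
        assert ellipse_test(cloud).inside

    def test_distant_cloud_closed_form(self):
        rng = np.random.default_rng(1)
        cloud = np.array([5.0, 3.0]) + rng.normal(size=(20000, 2))
        test = ellipse_test(cloud)
        # population distance of (0,1) from N((5,3), I) is 25 + 4 = 29
        assert test.mahalanobis_sq == pytest.approx(29.0, rel=0.05)
        assert not test.inside
        assert test.threshold == pytest.approx(5.9915, abs=1e-3)

    def test_chi2_calibration(self):
        rng = np.random.default_rng(2)
        mean = np.array([0.0, 1.0])
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        pts = rng.multivariate_normal(mean, cov, size=10_000)
        diff = pts - mean
        sol = np.linalg.solve(cov, diff.T)
        d2 = (diff.T * sol).sum(axis=0)
        frac = float((d2 <= CHI2_95_DF2).mean())
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_axis_order_invariance(self):
        rng = np.random.default_rng(3)
        cloud = rng.multivariate_normal([0.3, 0.9], [[0.2, 0.05], [0.05, 0.1]], size=500)
        t1 = ellipse_test(cloud, point=(0.0, 1.0))
        t2 = ellipse_test(cloud[:, ::-1], point=(1.0, 0.0))
        assert t1.mahalanobis_sq == pytest.approx(t2.mahalanobis_sq)
        assert t1.inside == t2.inside

    def test_collinear_cloud_point_on_line(self):
        # degenerate cloud along intercept = 1 - slope; (0, 1) lies on it
        b = np.random.default_rng(4).normal(1.0, 0.1, size=400)
        cloud = np.column_stack([1.0 - b, b])
        test = ellipse_test(cloud)
        assert test.rank == 1
        assert test.threshold == pytest.approx(stats.chi2.ppf(0.95, 1))
        assert test.inside  # slope 1 well within the 1-D spread

    def test_collinear_cloud_point_off_line(self):
        b = np.random.default_rng(5).normal(1.0, 0.1, size=400)
        cloud = np.column_stack([5.0 - b, b])  # line intercept = 5 - slope
        test = ellipse_test(cloud, point=(0.0, 1.0))
        assert not test.inside
        assert math.isinf(test.mahalanobis_sq)

    def test_too_few_points(self):
        with pytest.raises(DegenerateFitError):
            ellipse_test(np.array([[0.0, 1.0], [0.1, 1.1]]))

    def test_coverage_of_plugin_ellipse(self):
        """Clouds truly centered on (0,1): the plug-in 95% ellipse contains
        the point in at least ~93% of meta-replicates."""
        rng = np.random.default_rng(6)
        hits = 0
        n_meta = 500
        for _ in range(n_meta):
            cloud = rng.multivariate_normal([0, 1], [[0.5, 0.2], [0.2, 0.3]], size=1000)
            if ellipse_test(cloud).inside:
                hits += 1
        assert hits / n_meta >= 0.93
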