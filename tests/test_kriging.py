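"""Variogram estimation/fitting, ordinary kriging, and the odds-ratio surface."""

import numpy as np
import pytest

import smcair
from smcair import (VariogramModel, empirical_variogram, fit_variogram,
                    odds_ratio_surface, ordinary_krige)
from smcair.errors import InvalidArgumentError, SmcairError
from smcair.geo_core import Raster


class TestEmpiricalVariogram:
    def test_two_points_single_bin(self):
        emp = empirical_variogram(np.array([[0, 0], [100, 0]]),
                                  np.array([0.0, 1.0]), n_bins=1, max_lag=200)
        assert len(emp.lags) == 1
        assert emp.semivariance[0] == pytest.approx(0.5)
        assert emp.pair_counts[0] == 1

    def test_constant_values_zero_gamma(self, rng):
        pts = rng.uniform(0, 1000, (20, 2))
        emp = empirical_variogram(pts, np.full(20, 3.3))
        assert np.allclose(emp.semivariance, 0.0)

    def test_matches_pair_loop_oracle(self, rng):
        pts = rng.uniform(0, 1000, (30, 2))
        vals = rng.random(30)
        n_bins, max_lag = 8, 700.0
        emp = empirical_variogram(pts, vals, n_bins=n_bins, max_lag=max_lag)
        edges = np.linspace(0, max_lag, n_bins + 1)
        got = dict(zip(np.round(emp.lags, 9), emp.semivariance))
        for b in range(n_bins):
            sq, d_list = [], []
            for i in range(30):
                for j in range(i + 1, 30):
                    d = np.hypot(*(pts[i] - pts[j]))
                    lo, hi = edges[b], edges[b + 1]
                    inside = (lo <= d < hi) if b < n_bins - 1 else (lo <= d <= hi)
                    if inside:
                        sq.append((vals[i] - vals[j]) ** 2)
                        d_list.append(d)
            if sq:
                key = round(float(np.mean(d_list)), 9)
                assert got[key] == pytest.approx(0.5 * np.mean(sq), abs=1e-12)

    def test_coincident_points_error(self):
        with pytest.raises(SmcairError):
            empirical_variogram(np.zeros((5, 2)), np.arange(5.0))


class TestFitVariogram:
    def test_parameter_recovery_exponential(self):
        truth = VariogramModel("exponential", nugget=0.05, partial_sill=0.20,
                               range_=3000.0)
        lags = np.linspace(200, 8000, 12)
        emp = smcair.EmpiricalVariogram(lags=lags, semivariance=truth(lags),
                                        pair_counts=np.full(12, 50))
        fit = fit_variogram(emp, "exponential")
        assert fit.nugget == pytest.approx(0.05, rel=0.15, abs=0.01)
        assert fit.partial_sill == pytest.approx(0.20, rel=0.15)
        assert fit.range_ == pytest.approx(3000.0, rel=0.15)

    def test_pure_nugget_limit(self):
        lags = np.linspace(100, 5000, 10)
        emp = smcair.EmpiricalVariogram(lags=lags,
                                        semivariance=np.full(10, 0.25),
                                        pair_counts=np.full(10, 30))
        fit = fit_variogram(emp)
        assert fit.partial_sill <= 0.01

    def test_too_few_bins(self):
        emp = smcair.EmpiricalVariogram(lags=np.array([1.0, 2.0]),
                                        semivariance=np.array([0.1, 0.2]),
                                        pair_counts=np.array([3, 3]))
        with pytest.raises(InvalidArgumentError):
            fit_variogram(emp)


class TestOrdinaryKrige:
    def test_exact_interpolation_with_zero_nugget(self, rng):
        pts = rng.uniform(100, 900, (12, 2))
        vals = rng.random(12)
        vg = VariogramModel("exponential", nugget=0.0, partial_sill=0.3,
                            range_=500.0)
        # grid whose cell centers include the data points is impractical;
        # instead predict on a tiny grid centered at each data point
        for p, v in zip(pts, vals):
            g = smcair.GridSpec(x_min=p[0] - 0.5, y_max=p[1] + 0.5,
                                n_rows=1, n_cols=1, cell_size=1.0)
            pred = ordinary_krige(pts, vals, vg, g)
            assert pred.values[0, 0] == pytest.approx(v, abs=1e-8)

    def test_constant_field_reproduced(self, rng):
        pts = rng.uniform(0, 1000, (15, 2))
        vg = VariogramModel("spherical", nugget=0.1, partial_sill=0.2, range_=400.0)
        g = smcair.make_grid((0, 0, 1000, 1000), 100)
        pred = ordinary_krige(pts, np.full(15, 2.5), vg, g)
        assert np.allclose(pred.values, 2.5, atol=1e-10)

    def test_matches_dense_solve_oracle(self, rng):
        """5 points, one prediction cell: weights and prediction from an
        independently coded full linear solve."""
        pts = rng.uniform(0, 100, (5, 2))
        vals = rng.random(5)
        vg = VariogramModel("exponential", nugget=0.02, partial_sill=0.15,
                            range_=60.0)
        g = smcair.GridSpec(x_min=40.0, y_max=60.0, n_rows=1, n_cols=1, cell_size=1.0)
        pred = ordinary_krige(pts, vals, vg, g)

        def gamma(h):
            return 0.0 if h == 0 else 0.02 + 0.15 * (1 - np.exp(-3 * h / 60.0))

        A = np.ones((6, 6))
        A[5, 5] = 0.0
        for i in range(5):
            for j in range(5):
                A[i, j] = gamma(np.hypot(*(pts[i] - pts[j])))
        target = np.array([40.5, 59.5])
        b = np.array([gamma(np.hypot(*(pts[i] - target))) for i in range(5)] + [1.0])
        lam = np.linalg.solve(A, b)
        assert abs(lam[:5].sum() - 1.0) < 1e-9          # unbiasedness
        assert pred.values[0, 0] == pytest.approx(float(lam[:5] @ vals), abs=1e-9)

    def test_duplicates_with_nugget_regularized(self):
        pts = np.array([[0, 0], [0, 0], [50, 50], [80, 20]], float)
        vals = np.array([1.0, 0.0, 1.0, 0.0])
        vg = VariogramModel("exponential", nugget=0.1, partial_sill=0.2, range_=60.0)
        g = smcair.make_grid((0, 0, 100, 100), 25)
        pred = ordinary_krige(pts, vals, vg, g)
        assert np.isfinite(pred.values).all()

    def test_duplicates_zero_nugget_fail_mode(self):
        pts = np.array([[0, 0], [0, 0], [50, 50]], float)
        vals = np.array([1.0, 0.0, 1.0])
        vg = VariogramModel("exponential", nugget=0.0, partial_sill=0.2, range_=60.0)
        g = smcair.make_grid((0, 0, 100, 100), 50)
        with pytest.raises(SmcairError, match="singular"):
            ordinary_krige(pts, vals, vg, g, on_singular="fail")
        # default jitters instead
        pred = ordinary_krige(pts, vals, vg, g)
        assert np.isfinite(pred.values).all()


class TestORSurface:
    def make_p(self, grid, values):
        return Raster(grid=grid, values=values, kind="continuous")

    def test_baseline_proportion_gives_or_one(self, small_grid):
        p = self.make_p(small_grid, np.full(small_grid.shape, 164 / 373))
        ors = odds_ratio_surface(p, 164, 209)
        assert np.allclose(ors.OR.values, 1.0, atol=1e-12)

    def test_hand_arithmetic(self, small_grid):
        p = self.make_p(small_grid, np.full(small_grid.shape, 0.6))
        ors = odds_ratio_surface(p, 100, 100)   # baseline odds 1
        assert np.allclose(ors.OR.values, 1.5)

    def test_clipping_keeps_or_positive(self, small_grid):
        p = self.make_p(small_grid, np.zeros(small_grid.shape))
        ors = odds_ratio_surface(p, 164, 209)
        assert (ors.OR.values > 0).all()
        assert np.allclose(ors.p_hat.values, 1e-6)

    def test_or_monotone_in_p(self, small_grid, rng):
        from scipy.stats import spearmanr
        p = self.make_p(small_grid, rng.uniform(0.05, 0.95, small_grid.shape))
        ors = odds_ratio_surface(p, 164, 209)
        rho, _ = spearmanr(p.values.ravel(), ors.OR.values.ravel())
        assert rho == pytest.approx(1.0)

    def test_zero_controls_rejected(self, small_grid):
        p = self.make_p(small_grid, np.full(small_grid.shape, 0.5))
        with pytest.raises(InvalidArgumentError):
            odds_ratio_surface(p, 10, 0)
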