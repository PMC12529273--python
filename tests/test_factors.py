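"""Factor rasters: distances, classification, kernel density, rescaling."""

import numpy as np
import pytest

import smcair
from smcair import (ClassBreaks, KDEConfig, LandUseScoreMap, classify_by_breaks,
                    distance_raster, fog_scores, kde_raster, landuse_scores,
                    rescale_minmax_1_3)
from smcair.errors import InvalidArgumentError, SmcairError
from smcair.geo_core import FeatureSet, Raster


def point_set(coords):
    return FeatureSet("point", [np.array([c], float) for c in coords])


class TestDistanceRaster:
    def test_single_point_345_triangle(self):
        # grid whose first cell center is (30, 40): distance to origin = 50
        g = smcair.GridSpec(x_min=25.0, y_max=45.0, n_rows=1, n_cols=1, cell_size=10.0)
        d = distance_raster(point_set([(0.0, 0.0)]), g)
        assert d.values[0, 0] == pytest.approx(50.0, abs=1e-6)

    def test_perpendicular_to_segment(self):
        g = smcair.GridSpec(x_min=45.0, y_max=35.0, n_rows=1, n_cols=1, cell_size=10.0)
        seg = FeatureSet("polyline", [np.array([[0.0, 0.0], [100.0, 0.0]])])
        d = distance_raster(seg, g)
        assert d.values[0, 0] == pytest.approx(30.0, abs=1e-6)

    def test_matches_bruteforce_point_oracle(self, rng):
        g = smcair.make_grid((0, 0, 2000, 2000), 100)
        pts = rng.uniform(0, 2000, (5, 2))
        d = distance_raster(point_set(pts), g)
        centers = g.center_grid()
        brute = np.min(np.linalg.norm(centers[:, None, :] - pts[None], axis=2), axis=1)
        assert np.allclose(d.values.ravel(), brute, atol=1e-6)

    def test_monotone_adding_features(self, rng):
        g = smcair.make_grid((0, 0, 2000, 2000), 200)
        pts = rng.uniform(0, 2000, (4, 2))
        d4 = distance_raster(point_set(pts), g).values
        d5 = distance_raster(point_set(np.vstack([pts, [[777.0, 333.0]]])), g).values
        assert (d5 <= d4 + 1e-12).all()

    def test_translation_invariance_of_classes(self, rng):
        pts = rng.uniform(0, 5000, (6, 2))
        g = smcair.make_grid((0, 0, 5000, 5000), 250)
        shift = np.array([12345.0, -6789.0])
        g2 = smcair.GridSpec(g.x_min + shift[0], g.y_max + shift[1],
                             g.n_rows, g.n_cols, g.cell_size)
        cb = ClassBreaks((2000.0, 4000.0))
        c1 = classify_by_breaks(distance_raster(point_set(pts), g), cb)
        c2 = classify_by_breaks(distance_raster(point_set(pts + shift), g2), cb)
        assert np.array_equal(c1.values, c2.values)

    def test_empty_features_error(self, small_grid):
        with pytest.raises(SmcairError, match="all-low"):
            distance_raster(FeatureSet("point", []), small_grid)


class TestClassifyByBreaks:
    def setup_method(self):
        self.grid = smcair.GridSpec(0, 10, 1, 3, 1.0)

    def classify(self, vals, breaks):
        r = Raster(grid=self.grid, values=np.array([vals], float))
        return classify_by_breaks(r, ClassBreaks(breaks)).values[0]

    def test_pollutant_source_distances(self):
        assert self.classify([1500, 3000, 5000], (2000, 4000)).tolist() == [3, 2, 1]

    def test_boundaries_belong_to_moderate(self):
        assert self.classify([2000, 4000, 1999.999], (2000, 4000)).tolist() == [2, 2, 3]

    def test_road_distances(self):
        assert self.classify([50, 300, 301], (100, 300)).tolist() == [3, 2, 1]

    def test_nonincreasing_breaks_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ClassBreaks((300.0, 100.0))

    def test_nodata_propagates(self):
        r = Raster(grid=self.grid, values=np.array([[1.0, -9999.0, 9.0]]),
                   nodata=-9999.0)
        out = classify_by_breaks(r, ClassBreaks((2.0, 5.0)))
        assert out.values[0].tolist() == [3, 0, 1] and out.nodata == 0


class TestKDE:
    def test_peak_value_single_point(self):
        # quartic kernel peak = 3/(pi h^2) per m^2 -> 3/pi per km^2 at h=1000
        g = smcair.make_grid((0, 0, 4000, 4000), 10)
        pts = point_set([(2005.0, 1995.0)])  # exactly a cell center
        d = kde_raster(pts, KDEConfig(bandwidth=1000.0), g)
        row, col = g.xy_to_rowcol(2005.0, 1995.0)
        assert d.values[row, col] == pytest.approx(3 / np.pi, rel=1e-9)

    def test_unit_mass_interior_point(self):
        g = smcair.make_grid((0, 0, 3000, 3000), 10)
        d = kde_raster(point_set([(1500.0, 1500.0)]), KDEConfig(bandwidth=500.0), g)
        mass = d.values.sum() * g.cell_area_m2 / 1e6
        assert mass == pytest.approx(1.0, abs=0.01)

    def test_matches_double_loop_oracle(self, rng):
        g = smcair.make_grid((0, 0, 1000, 1000), 10)
        pts = rng.uniform(0, 1000, (10, 2))
        h = 300.0
        d = kde_raster(point_set(pts), KDEConfig(bandwidth=h), g)
        centers = g.center_grid()
        dist = np.linalg.norm(centers[:, None, :] - pts[None], axis=2)
        u2 = (dist / h) ** 2
        brute = np.where(u2 < 1, 3 / (np.pi * h * h) * (1 - u2) ** 2, 0).sum(axis=1) * 1e6
        assert np.allclose(d.values.ravel(), brute, atol=1e-9)
        assert (d.values >= 0).all()

    def test_zero_points_warns_and_zeroes(self, small_grid):
        with pytest.warns(UserWarning, match="zero points"):
            d = kde_raster(FeatureSet("point", []), KDEConfig(), small_grid)
        assert (d.values == 0).all()


class TestRescale:
    def test_endpoints_and_midpoint(self, small_grid):
        vals = np.zeros(small_grid.shape)
        vals.ravel()[:3] = [0.0, 5.0, 10.0]
        vals.ravel()[3:] = 5.0
        out = rescale_minmax_1_3(Raster(grid=small_grid, values=vals))
        assert out.values.ravel()[:3].tolist() == [1.0, 2.0, 3.0]

    def test_constant_maps_to_low(self, small_grid):
        out = rescale_minmax_1_3(Raster(grid=small_grid,
                                        values=np.full(small_grid.shape, 7.0)))
        assert (out.values == 1.0).all()

    def test_order_preserved_and_range(self, small_grid, rng):
        from scipy.stats import spearmanr
        vals = rng.random(small_grid.shape)
        out = rescale_minmax_1_3(Raster(grid=small_grid, values=vals))
        assert out.values.min() == 1.0 and out.values.max() == 3.0
        rho, _ = spearmanr(vals.ravel(), out.values.ravel())
        assert rho == pytest.approx(1.0)
        # direct formula
        expect = 1 + 2 * (vals - vals.min()) / (vals.max() - vals.min())
        assert np.allclose(out.values, expect)


class TestCategoricalFactors:
    def test_landuse_mapping(self, small_grid, rng):
        codes = rng.integers(1, 4, small_grid.shape)
        lu = Raster(grid=small_grid, values=codes, nodata=0, kind="categorical")
        out = landuse_scores(lu)
        assert np.array_equal(out.values, codes)  # default map is identity on codes

    def test_unmapped_category_error(self, small_grid):
        lu = Raster(grid=small_grid, values=np.full(small_grid.shape, 9, dtype=int),
                    nodata=0, kind="categorical")
        with pytest.raises(SmcairError, match="9"):
            landuse_scores(lu, LandUseScoreMap(mapping={1: 1}))

    def test_fog_inside_outside(self, small_grid):
        ring = np.array([[0, 0], [500, 0], [500, 400], [0, 400], [0, 0]], float)
        fog = FeatureSet("polygon", [ring])
        out = fog_scores(fog, small_grid)
        centers = small_grid.center_grid()
        inside = ((centers[:, 0] < 500) & (centers[:, 1] < 400)).reshape(small_grid.shape)
        assert (out.values[inside] == 3).all() and (out.values[~inside] == 1).all()

    def test_empty_fog_all_low(self, small_grid):
        out = fog_scores(FeatureSet("polygon", []), small_grid)
        assert (out.values == 1).all()


class TestClassificationProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(min_value=0, max_value=1e5, allow_nan=False),
                    min_size=1, max_size=12),
           st.tuples(st.floats(1, 1e4), st.floats(1, 1e4)).filter(
               lambda b: b[0] < b[1]))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_classes_always_in_123_and_monotone(self, values, breaks):
        grid = smcair.GridSpec(0, 1, 1, len(values), 1.0)
        r = Raster(grid=grid, values=np.array([values]))
        out = classify_by_breaks(r, ClassBreaks(tuple(breaks))).values[0]
        assert set(out.tolist()) <= {1, 2, 3}
        # near_is_high: larger distance never yields a higher class
        order = np.argsort(values)
        assert (np.diff(out[order]) <= 0).all()


def test_all_factor_outputs_in_range(factor_scores):
    for name, r in factor_scores.items():
        v = r.valid_values()
        assert v.min() >= 1 and v.max() <= 3, name
        if r.kind == "class":
            assert set(np.unique(v)) <= {1, 2, 3}, name
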