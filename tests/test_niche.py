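"""Environmental-space geometry: hulls, centroids, clipping, density profiles."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon

from conftest import make_stack
from sdmshift.evaluate import BinaryMap
from sdmshift.grid import Grid
from sdmshift.niche import (compare_hulls, convex_hull_2d, density_profile,
                            occupied_env_points)


class TestConvexHull:
    def test_unit_square_with_interior_point(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)]
        h = convex_hull_2d(pts)
        assert h.area == pytest.approx(1.0, abs=1e-12)
        assert h.centroid == pytest.approx((0.5, 0.5), abs=1e-12)
        assert h.n_vertices == 4

    def test_triangle_closed_forms(self):
        h = convex_hull_2d([(0, 0), (2, 0), (0, 2)])
        assert h.area == pytest.approx(2.0, abs=1e-12)
        assert h.centroid == pytest.approx((2 / 3, 2 / 3), abs=1e-12)

    def test_collinear_points_degenerate(self):
        h = convex_hull_2d([(0, 0), (1, 1), (2, 2)])
        assert h.degenerate and h.area == 0.0
        assert h.centroid == pytest.approx((1.0, 1.0))

    def test_single_point(self):
        h = convex_hull_2d([(3.0, 4.0)])
        assert h.degenerate and h.centroid == (3.0, 4.0)

    def test_invariant_under_permutation_and_duplication(self, rng):
        pts = rng.normal(size=(40, 2))
        h1 = convex_hull_2d(pts)
        pts2 = np.vstack([pts[::-1], pts[:10]])
        h2 = convex_hull_2d(pts2)
        assert h1.area == pytest.approx(h2.area, rel=1e-12)
        assert h1.centroid == pytest.approx(h2.centroid, rel=1e-12)

    def test_interior_point_never_changes_hull(self, rng):
        pts = rng.normal(size=(30, 2))
        h1 = convex_hull_2d(pts)
        interior = pts.mean(axis=0)  # centroid of points lies inside the hull
        h2 = convex_hull_2d(np.vstack([pts, interior]))
        np.testing.assert_allclose(h1.vertices, h2.vertices)

    def test_matches_scipy_qhull_on_random_clouds(self, rng):
        for _ in range(25):
            pts = rng.normal(size=(rng.integers(3, 60), 2))
            ours = convex_hull_2d(pts)
            if ours.degenerate:
                continue
            ref = ConvexHull(pts)
            assert ours.area == pytest.approx(ref.volume, rel=1e-10)
            assert ours.n_vertices == len(ref.vertices)


class TestCompareHulls:
    def _square(self, dx=0.0, dy=0.0, scale=1.0, period="p"):
        c = 0.5  # scale about the square's center
        pts = [((x - c) * scale + c + dx, (y - c) * scale + c + dy)
               for x, y in [(0, 0), (1, 0), (1, 1), (0, 1)]]
        return convex_hull_2d(pts, period=period)

    def test_identical_hulls(self):
        cmp_ = compare_hulls({"a": self._square(), "b": self._square()})
        r = cmp_["a vs b"]
        assert r["displacement_magnitude"] == 0.0
        assert r["area_ratio"] == 1.0
        assert r["intersection_area"] == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_translation(self):
        cmp_ = compare_hulls({"a": self._square(), "b": self._square(dx=2.0)})
        r = cmp_["a vs b"]
        assert r["intersection_area"] == 0.0
        assert r["displacement"] == pytest.approx((2.0, 0.0), abs=1e-12)

    def test_doubling_scale_quadruples_area(self):
        cmp_ = compare_hulls({"a": self._square(), "b": self._square(scale=2.0)})
        assert cmp_["a vs b"]["area_ratio"] == pytest.approx(4.0, rel=1e-12)

    def test_intersection_bounded_by_min_area(self, rng):
        for _ in range(20):
            a = convex_hull_2d(rng.normal(size=(20, 2)))
            b = convex_hull_2d(rng.normal(size=(20, 2)) + 0.5)
            r = compare_hulls({"a": a, "b": b})["a vs b"]
            assert r["intersection_area"] <= min(a.area, b.area) + 1e-12
            # independent clipping oracle
            ref = Polygon(a.vertices).intersection(Polygon(b.vertices)).area
            assert r["intersection_area"] == pytest.approx(ref, abs=1e-12)

    def test_degenerate_hull_keeps_displacement(self):
        seg = convex_hull_2d([(0, 0), (0, 1)])
        sq = self._square()
        r = compare_hulls({"a": seg, "b": sq})["a vs b"]
        assert r["intersection_area"] == 0.0
        assert np.isfinite(r["displacement_magnitude"])


class TestOccupiedEnvPoints:
    def _setup(self, suitable):
        grid = Grid(4, 4, 0.0, 0.0, 1.0)
        stack = make_stack(grid, {"t": np.arange(16, dtype=float).reshape(4, 4),
                                  "s": np.ones((4, 4))})
        binary = BinaryMap(grid=grid, suitable=suitable,
                           mask=np.zeros((4, 4), bool), threshold=0.5)
        return grid, stack, binary

    def test_no_suitable_cells_empty(self):
        _, stack, binary = self._setup(np.zeros((4, 4), bool))
        pts = occupied_env_points(binary, stack, ["t", "s"], (0, 4, 0, 4))
        assert pts.shape == (0, 2)

    def test_single_cell_single_point(self):
        suit = np.zeros((4, 4), bool)
        suit[1, 2] = True
        _, stack, binary = self._setup(suit)
        pts = occupied_env_points(binary, stack, ["t", "s"], (0, 4, 0, 4))
        assert pts.tolist() == [[6.0, 1.0]]

    def test_checkerboard_contributes_half(self):
        suit = (np.add.outer(np.arange(4), np.arange(4)) % 2 == 0)
        _, stack, binary = self._setup(suit)
        pts = occupied_env_points(binary, stack, ["t"], (0, 4, 0, 4))
        assert len(pts) == 8

    def test_focal_box_restricts(self):
        suit = np.ones((4, 4), bool)
        _, stack, binary = self._setup(suit)
        # box covering only the northern half (lat 2..4 = rows 0..1)
        pts = occupied_env_points(binary, stack, ["t"], (2.0, 4.0, 0.0, 4.0))
        assert sorted(p[0] for p in pts) == list(range(8))


class TestDensityProfile:
    def test_single_value_peaks_at_one_exactly_there(self):
        prof = density_profile(np.array([2.5]), predictor="t")
        assert prof.density.max() == 1.0
        assert prof.peak() == pytest.approx(2.5, abs=1e-12)

    def test_symmetric_bimodal_gives_symmetric_profile(self):
        v = np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])
        grid_pts = np.linspace(-3, 3, 301)
        prof = density_profile(v, grid_pts, bandwidth=0.3)
        np.testing.assert_allclose(prof.density, prof.density[::-1], atol=1e-9)

    def test_standard_normal_peak_near_zero(self):
        v = np.random.default_rng(1).normal(size=10_000)
        prof = density_profile(v)
        assert abs(prof.peak()) < 0.1

    def test_scaled_to_max_one(self, rng):
        prof = density_profile(rng.normal(size=100))
        assert prof.density.max() == 1.0
        assert prof.density.min() >= 0.0

    def test_zero_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            density_profile(np.array([1.0, 2.0]), bandwidth=0.0)
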