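"""Per-structure and per-nucleus measurements."""

import numpy as np
import pytest
from shapely.geometry import Polygon

import clutchmap as cm
from _oracles import brute_proximity


class TestPeripheryZscore:
    def test_boundary_blinks_share_minus_mu_over_sigma(self, square_roi):
        blinks = cm.BlinkMap(np.array([[0.0, 50.0], [100.0, 20.0], [30.0, 0.0]]), square_roi)
        z, _ = cm.periphery_zscore(blinks)
        mu, sd = square_roi.grid_boundary_stats()
        np.testing.assert_allclose(z, -mu / sd, atol=1e-12)

    def test_disc_grid_moments_match_analytic(self):
        # uniform disc of radius R: d = R - r has mean R/3 and
        # variance R^2/18 (E[d^2] = R^2/6)
        R = 2000.0
        roi = cm.make_nucleus(
            cm.NucleusShapeSpec(base_radius=R, irregularity=0.0, n_vertices=512, seed=0)
        )
        mu, sd = roi.grid_boundary_stats()
        assert mu == pytest.approx(R / 3, rel=0.01)
        assert sd == pytest.approx(R / np.sqrt(18), rel=0.01)

    def test_uniform_blinks_mean_zero(self, irregular_roi):
        means = [
            cm.periphery_zscore(cm.sample_csr(irregular_roi, 0.0008, seed=s))[1]
            for s in range(10)
        ]
        means = np.asarray(means)
        sem = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * sem + 1e-3

    def test_monte_carlo_reference_agrees_with_grid(self, irregular_roi):
        blinks = cm.sample_csr(irregular_roi, 0.0005, seed=42)
        _, z_grid = cm.periphery_zscore(blinks)
        _, z_mc = cm.periphery_zscore(blinks, monte_carlo=40_000)
        assert z_mc == pytest.approx(z_grid, abs=0.03)


class TestStructureBoundary:
    def test_unit_square_corners_convex_case(self):
        xy = np.array([[0, 0], [50, 0], [50, 50], [0, 50]], float)
        poly, area = cm.structure_boundary(xy)
        assert area == pytest.approx(2500.0)

    def test_c_shape_is_concave(self):
        # points along a C: alpha shape must hug the arc, beating the hull
        t = np.linspace(0.25 * np.pi, 1.75 * np.pi, 40)
        outer = np.column_stack([100 * np.cos(t), 100 * np.sin(t)])
        inner = np.column_stack([60 * np.cos(t[::-1]), 60 * np.sin(t[::-1])])
        xy = np.vstack([outer, inner])
        poly, area = cm.structure_boundary(xy)
        hull_area = Polygon(xy).convex_hull.area
        assert area < hull_area

    def test_all_points_covered(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            xy = rng.uniform(0, 80, (int(rng.integers(10, 60)), 2))
            poly, _ = cm.structure_boundary(xy)
            from shapely.geometry import MultiPoint

            assert poly.covers(MultiPoint(xy))

    def test_degenerate_inputs_flagged(self):
        assert cm.structure_boundary(np.array([[0.0, 0.0], [1.0, 1.0]])) == (None, 0.0)
        collinear = np.column_stack([np.arange(5.0), np.arange(5.0)])
        poly, area = cm.structure_boundary(collinear)
        assert poly is None and area == 0.0


class TestApproxDiameter:
    def test_equivalent_circle(self):
        assert cm.approx_diameter(np.pi * 155.0**2) == pytest.approx(310.0)

    def test_zero_area(self):
        assert cm.approx_diameter(0.0) == 0.0

    def test_sqrt2_scaling(self):
        a = 12345.0
        assert cm.approx_diameter(2 * a) == pytest.approx(np.sqrt(2) * cm.approx_diameter(a))


def _square_clutch(x0, y0, side=40.0):
    xy = np.array(
        [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side],
         [x0 + side / 2, y0 + side / 2]]
    )
    c = cm.Clutch(blink_indices=np.arange(5), xy=xy)
    c.compute_geometry()
    return c


class TestClutchProximity:
    def test_two_squares_50nm_apart(self):
        a, b = _square_clutch(0, 0), _square_clutch(90, 0)
        prox = cm.clutch_proximity([a, b])
        np.testing.assert_allclose(prox, [50.0, 50.0], atol=1e-9)

    def test_overlapping_polygons_zero(self):
        a, b = _square_clutch(0, 0), _square_clutch(20, 20)
        np.testing.assert_allclose(cm.clutch_proximity([a, b]), [0.0, 0.0])

    def test_line_of_clutches_matches_brute_force(self):
        clutches = [_square_clutch(i * 130.0, 0) for i in range(12)]
        prox = cm.clutch_proximity(clutches, n_neighbours=10)
        oracle = brute_proximity([c.boundary for c in clutches], n_neighbours=10)
        np.testing.assert_allclose(prox, oracle, atol=1e-9)

    def test_single_clutch_undefined(self):
        with pytest.raises(ValueError):
            cm.clutch_proximity([_square_clutch(0, 0)])


class TestSummariseNucleus:
    def test_weighted_mean_diameter_arithmetic(self, square_roi):
        # diameters {100, 300} with blink weights {10, 30} -> 250
        aggs = []
        for diam, n in ((100.0, 10), (300.0, 30)):
            c = cm.Clutch(blink_indices=np.arange(n), xy=np.zeros((n, 2)))
            a = cm.Aggregate(clutch_ids=[0], clutches=[c])
            a.area = np.pi * (diam / 2) ** 2
            a.approx_diameter = diam
            a.density = 0.01
            aggs.append(a)
        blinks = cm.BlinkMap(np.array([[50.0, 50.0]]), square_roi)
        s = cm.summarise_nucleus(blinks, [], aggs, square_roi)
        assert s.wmean_aggregate_diameter == pytest.approx(250.0)

    def test_area_fraction_ten_percent(self, square_roi):
        c = cm.Clutch(blink_indices=np.arange(3), xy=np.zeros((3, 2)))
        a = cm.Aggregate(clutch_ids=[0], clutches=[c])
        a.area = 0.10 * square_roi.area
        a.approx_diameter = cm.approx_diameter(a.area)
        a.density = 0.01
        blinks = cm.BlinkMap(np.array([[50.0, 50.0]]), square_roi)
        s = cm.summarise_nucleus(blinks, [], aggs := [a], square_roi)
        assert s.wmean_aggregate_area_fraction == pytest.approx(10.0)
        assert s.total_aggregate_area_fraction == pytest.approx(10.0)

    def test_ground_truth_recomputation(self, circle_roi):
        spec = cm.ClutchPatternSpec(
            n_clutches=12, clutch_radius=40, blinks_per_clutch=30,
            background_fraction=0.0, seed=77,
        )
        blinks, _ = cm.sample_clutch_pattern(circle_roi, spec)
        seg = cm.segment(blinks)
        s = cm.summarise_nucleus(blinks, seg.clutches, seg.aggregates, circle_roi)
        # hand recomputation from the structure lists
        assert s.mean_clutch_density == pytest.approx(
            np.mean([c.density for c in seg.clutches])
        )
        w = np.array([a.blink_count for a in seg.aggregates], float)
        assert s.wmean_aggregate_diameter == pytest.approx(
            np.average([a.approx_diameter for a in seg.aggregates], weights=w)
        )
        assert s.wmean_aggregate_area_fraction == pytest.approx(
            np.average(
                [100 * a.area / circle_roi.area for a in seg.aggregates], weights=w
            )
        )
        assert s.n_clutches == 12
        # equal blink counts: weighted means equal unweighted means
        assert s.wmean_aggregate_density == pytest.approx(
            np.mean([a.density for a in seg.aggregates])
        )

    def test_missing_fields_flagged_nan(self, square_roi):
        blinks = cm.BlinkMap(np.array([[50.0, 50.0]]), square_roi)
        s = cm.summarise_nucleus(blinks, [], [], square_roi)
        assert np.isnan(s.mean_clutch_density)
        assert np.isnan(s.wmean_aggregate_diameter)


class TestRigidMotionInvariance:
    def test_measurements_invariant_under_rotation_translation(self, circle_roi):
        spec = cm.ClutchPatternSpec(
            n_clutches=8, clutch_radius=40, blinks_per_clutch=25, seed=88
        )
        blinks, _ = cm.sample_clutch_pattern(circle_roi, spec)
        seg = cm.segment(blinks)
        s0 = cm.summarise_nucleus(blinks, seg.clutches, seg.aggregates, circle_roi)

        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = np.array([1234.5, -987.6])
        roi2 = cm.NucleusROI(circle_roi.vertices @ R.T + shift)
        blinks2 = cm.BlinkMap(blinks.xy @ R.T + shift, roi2)
        seg2 = cm.segment(blinks2)
        s1 = cm.summarise_nucleus(blinks2, seg2.clutches, seg2.aggregates, roi2)

        assert s1.mean_clutch_density == pytest.approx(s0.mean_clutch_density, rel=1e-6)
        assert s1.mean_clutch_proximity == pytest.approx(s0.mean_clutch_proximity, rel=1e-6)
        assert s1.wmean_aggregate_diameter == pytest.approx(s0.wmean_aggregate_diameter, rel=1e-6)
        # periphery z-score co-transforms with the ROI up to pixel-grid
        # realignment of the reference moments
        assert s1.mean_periphery_z == pytest.approx(s0.mean_periphery_z, abs=0.02)
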