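"""Synthetic-data generator: determinism, containment, calibration."""

import numpy as np
import pytest
from scipy.stats import kstest

import clutchmap as cm
from _oracles import polygon_is_simple, winding_number_inside


class TestMakeNucleus:
    def test_regular_polygon_approaches_circle_area(self):
        roi = cm.make_nucleus(
            cm.NucleusShapeSpec(base_radius=5000, irregularity=0.0, n_vertices=64, seed=0)
        )
        assert roi.area == pytest.approx(np.pi * 5000**2, rel=0.01)

    def test_same_seed_reproduces_vertices(self):
        spec = cm.NucleusShapeSpec(base_radius=3000, irregularity=0.4, n_vertices=48, seed=7)
        a, b = cm.make_nucleus(spec), cm.make_nucleus(spec)
        np.testing.assert_array_equal(a.vertices, b.vertices)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_irregular_polygon_is_simple(self, seed):
        roi = cm.make_nucleus(
            cm.NucleusShapeSpec(base_radius=2000, irregularity=0.3, n_vertices=40, seed=seed)
        )
        assert polygon_is_simple(roi.vertices)
        assert roi.area > 0

    def test_degenerate_vertex_count_rejected(self):
        with pytest.raises(ValueError):
            cm.NucleusShapeSpec(base_radius=1000, irregularity=0.1, n_vertices=7, seed=0)


class TestSampleCSR:
    def test_count_poisson_concentration(self, circle_roi):
        # density 0.001 on ~1.26e7 nm^2 -> ~12566 expected
        blinks = cm.sample_csr(circle_roi, 0.001, seed=11)
        mean = 0.001 * circle_roi.area
        assert abs(len(blinks) - mean) < 4 * np.sqrt(mean)

    def test_all_points_inside_polygon(self, irregular_roi):
        blinks = cm.sample_csr(irregular_roi, 0.0005, seed=12)
        inside = winding_number_inside(irregular_roi.vertices, blinks.xy[:200])
        assert inside.all()

    def test_mean_periphery_zscore_near_zero(self, irregular_roi):
        # CSR blinks average z ~ 0: the grid mean IS the uniform mean
        means = []
        for seed in range(20):
            blinks = cm.sample_csr(irregular_roi, 0.0008, seed=100 + seed)
            _, mz = cm.periphery_zscore(blinks)
            means.append(mz)
        means = np.asarray(means)
        sem = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * sem + 1e-3

    def test_nn_distance_matches_csr_theory(self, circle_roi):
        # NN distance CDF under CSR: 1 - exp(-lambda*pi*r^2), edge effects
        # negligible at this density/window ratio
        blinks = cm.sample_csr(circle_roi, 0.001, seed=13)
        assert len(blinks) > 8000
        from scipy.spatial import cKDTree

        d, _ = cKDTree(blinks.xy).query(blinks.xy, k=2)
        nn = d[:, 1]
        lam = len(blinks) / circle_roi.area
        stat, _ = kstest(nn, lambda r: 1 - np.exp(-lam * np.pi * r**2))
        assert stat < 0.02

    def test_density_must_be_positive(self, circle_roi):
        with pytest.raises(ValueError):
            cm.sample_csr(circle_roi, 0.0, seed=0)


class TestClutchPattern:
    def test_exact_recovery_by_segmentation(self, circle_roi):
        spec = cm.ClutchPatternSpec(
            n_clutches=20, clutch_radius=40, blinks_per_clutch=30,
            background_fraction=0.0, seed=21,
        )
        blinks, labels = cm.sample_clutch_pattern(circle_roi, spec)
        seg = cm.segment(blinks)
        assert len(seg.clutches) == 20
        # membership: each recovered clutch maps to exactly one truth label,
        # and together they cover every generated blink
        seen = {}
        for c in seg.clutches:
            truth = np.unique(labels[seg.kept_indices[c.blink_indices]])
            assert len(truth) == 1
            seen[int(truth[0])] = c.n_blinks
        assert sorted(seen) == list(range(20))
        assert all(n == 30 for n in seen.values())

    def test_blinks_per_clutch_exact_without_background(self, circle_roi):
        spec = cm.ClutchPatternSpec(
            n_clutches=5, clutch_radius=40, blinks_per_clutch=17,
            background_fraction=0.0, seed=22,
        )
        blinks, labels = cm.sample_clutch_pattern(circle_roi, spec)
        counts = np.bincount(labels)
        assert (counts == 17).all()
        assert len(blinks) == 5 * 17

    def test_background_fraction_of_total(self, circle_roi):
        spec = cm.ClutchPatternSpec(
            n_clutches=10, clutch_radius=40, blinks_per_clutch=30,
            background_fraction=0.25, seed=23,
        )
        blinks, labels = cm.sample_clutch_pattern(circle_roi, spec)
        frac = (labels == -1).mean()
        assert frac == pytest.approx(0.25, abs=0.01)

    def test_all_blinks_inside_nucleus(self, irregular_roi):
        spec = cm.ClutchPatternSpec(n_clutches=8, clutch_radius=40, blinks_per_clutch=25, seed=24)
        blinks, _ = cm.sample_clutch_pattern(irregular_roi, spec)
        assert irregular_roi.contains(blinks.xy[:, 0], blinks.xy[:, 1]).all()

    def test_aggregation_radius_groups_centres(self, circle_roi):
        spec = cm.ClutchPatternSpec(
            n_clutches=12, clutch_radius=40, blinks_per_clutch=10,
            aggregation_radius=300.0, seed=25,
        )
        blinks, _ = cm.sample_clutch_pattern(circle_roi, spec)
        centres = blinks.clutch_centres
        agg = blinks.aggregate_labels
        # at least one aggregate holds >1 clutch, and its centres sit within
        # 2x the aggregation radius of one another
        sizes = np.bincount(agg)
        assert (sizes > 1).any()
        for lab in np.flatnonzero(sizes > 1):
            sub = centres[agg == lab]
            d = np.linalg.norm(sub[:, None] - sub[None, :], axis=-1)
            assert d.max() <= 2 * 300.0 + 1e-9

    def test_infeasible_packing_raises(self):
        small = cm.make_nucleus(
            cm.NucleusShapeSpec(base_radius=600, irregularity=0.0, n_vertices=32, seed=0)
        )
        with pytest.raises(cm.synthetic.PackingError):
            cm.sample_clutch_pattern(
                small,
                cm.ClutchPatternSpec(n_clutches=40, clutch_radius=40, blinks_per_clutch=5, seed=1),
            )

    def test_determinism(self, circle_roi):
        spec = cm.ClutchPatternSpec(n_clutches=6, clutch_radius=40, blinks_per_clutch=12, seed=26)
        a, la = cm.sample_clutch_pattern(circle_roi, spec)
        b, lb = cm.sample_clutch_pattern(circle_roi, spec)
        np.testing.assert_array_equal(a.xy, b.xy)
        np.testing.assert_array_equal(la, lb)


class TestRadialBias:
    def test_zero_exponent_is_csr(self, irregular_roi):
        blinks = cm.sample_radial_bias(
            irregular_roi, cm.RadialBiasSpec(density=0.0008, bias_exponent=0.0), seed=31
        )
        _, mz = cm.periphery_zscore(blinks)
        assert abs(mz) < 0.05

    def test_strong_bias_is_peripheral(self, irregular_roi):
        blinks = cm.sample_radial_bias(
            irregular_roi, cm.RadialBiasSpec(density=0.0008, bias_exponent=3.0), seed=32
        )
        _, mz = cm.periphery_zscore(blinks)
        assert mz < -0.3

    def test_zscore_decreases_with_exponent(self, irregular_roi):
        zs = []
        for expo in (0.0, 1.0, 3.0):
            m = []
            for seed in range(5):
                blinks = cm.sample_radial_bias(
                    irregular_roi, cm.RadialBiasSpec(0.0008, expo), seed=40 + seed
                )
                m.append(cm.periphery_zscore(blinks)[1])
            zs.append(np.mean(m))
        assert zs[0] > zs[1] > zs[2]


class TestStampFrames:
    def test_uniform_profile_binomial_counts(self, circle_roi):
        blinks = cm.sample_csr(circle_roi, 0.0008, seed=51)
        table = cm.stamp_frames(blinks, n_frames=100, seed=52)
        counts = np.bincount(table["frame"], minlength=101)[1:]
        n, p = len(blinks), 1 / 100
        sd = np.sqrt(n * p * (1 - p))
        assert (np.abs(counts - n * p) < 6 * sd).all()
        assert table["frame"].between(1, 100).all()

    def test_marginal_coordinates_unchanged(self, circle_roi):
        blinks = cm.sample_csr(circle_roi, 0.0005, seed=53)
        table = cm.stamp_frames(blinks, n_frames=10, seed=54)
        np.testing.assert_array_equal(table[["x", "y"]].to_numpy(), blinks.xy)

    def test_csv_round_trip_preserves_values(self, circle_roi, tmp_path):
        blinks = cm.sample_csr(circle_roi, 0.0002, seed=55)
        table = cm.stamp_frames(blinks, n_frames=5, seed=56)
        path = tmp_path / "loc.csv"
        cm.write_localisations(table, path)
        back = cm.read_localisations(path)
        assert len(back) == len(table)
        np.testing.assert_array_equal(back["frame"], table["frame"])
        # file stores 4 decimals; round-trip is exact at that precision
        np.testing.assert_allclose(back["x"], table["x"], atol=5e-5)
        np.testing.assert_allclose(back["uncertainty"], table["uncertainty"], atol=5e-5)

    def test_front_loaded_profile_suffix_density_crosses_target(self, circle_roi):
        # with a decaying per-frame rate, the cumulative suffix count crosses
        # any target below the total at a k that plain arithmetic predicts
        blinks = cm.sample_csr(circle_roi, 0.002, seed=57)
        table = cm.stamp_frames(blinks, n_frames=50, seed=58, per_frame_rate="front_loaded")
        frames = table["frame"].to_numpy()
        area = circle_roi.area
        target = 0.001
        suffix = np.array([
            (frames >= 50 - k + 1).sum() / area for k in range(1, 51)
        ])
        crossing = np.flatnonzero(suffix >= target)
        assert len(crossing) > 0
        k_expected = crossing[0] + 1
        res = cm.homogenise(cm.BlinkMap(table[["x", "y"]].to_numpy(), circle_roi,
                                        frames=frames), target_density=target)
        assert abs(res.k - k_expected) <= 1  # argmin can sit either side of the crossing
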