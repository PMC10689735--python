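import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exmquant import synthdata
from exmquant.npc_symmetry import (
    EmptyParticleError,
    PointCloud,
    assign_sectors,
    corner_histogram,
    count_active_corners,
    detect_corners,
    estimate_orientation,
    image_to_pointcloud,
    trim_outliers,
    wrapped_angle_diff,
)


def _ideal_cloud(s=8, radius=53.5, n_per_corner=5, rotation=0.0):
    ang = rotation + 2 * np.pi * np.arange(s) / s
    pts = np.repeat(
        np.column_stack([radius * np.cos(ang), radius * np.sin(ang)]),
        n_per_corner, axis=0,
    )
    return PointCloud(pts, (0.0, 0.0))


class TestImageToPointcloud:
    def test_zero_image_raises(self):
        with pytest.raises(EmptyParticleError):
            image_to_pointcloud(np.zeros((16, 16)), 10.0, threshold_spec="abs:0.5")

    def test_single_bright_pixel(self):
        img = np.zeros((9, 9))
        img[3, 5] = 1.0
        cloud = image_to_pointcloud(img, 10.0, threshold_spec="abs:0.5")
        assert len(cloud) == 1
        np.testing.assert_allclose(cloud.points[0], [55.0, 35.0])
        np.testing.assert_allclose(cloud.center, (55.0, 35.0))

    def test_ring_centroid_within_one_pixel(self):
        px = 10.0
        img = synthdata.gen_ring_image(
            diameter=107.0, symmetry=8, unit_sigma=8.0, pixel_size=px,
            rotation=0.3, field_px=(32, 32),
        )
        cloud = image_to_pointcloud(img, px, threshold_spec="frac:0.2")
        true_center = (16 * px, 16 * px)
        assert abs(cloud.center[0] - true_center[0]) < px
        assert abs(cloud.center[1] - true_center[1]) < px

    def test_threshold_specs(self):
        img = np.zeros((8, 8))
        img[2, 2] = 10.0
        img[5, 5] = 2.0
        assert len(image_to_pointcloud(img, 1.0, "abs:1.0")) == 2
        assert len(image_to_pointcloud(img, 1.0, "frac:0.5")) == 1
        assert len(image_to_pointcloud(img, 1.0, 5.0)) == 1


class TestTrimOutliers:
    def test_keep_all_is_identity(self):
        cloud = _ideal_cloud()
        out = trim_outliers(cloud, keep_frac=1.0)
        np.testing.assert_array_equal(out.points, cloud.points)
        assert out.center == cloud.center

    def test_far_outlier_removed(self):
        pts = np.zeros((10, 2))
        pts[:9, 0] = np.linspace(1, 2, 9)
        pts[9] = [100.0, 0.0]
        cloud = PointCloud(pts, (0.0, 0.0))
        out = trim_outliers(cloud, keep_frac=0.9)
        assert len(out) == 9
        assert not np.any(out.points[:, 0] == 100.0)
        assert out.R < 100.0

    def test_tie_at_cut_radius_resolved_by_insertion_order(self):
        # radii: 1, 2, 2, 2; keep 0.5 -> ceil(2) = 2 points: the radius-1
        # point plus the FIRST radius-2 point by insertion index
        pts = np.array([[1.0, 0], [0, 2.0], [2.0, 0], [-2.0, 0]])
        cloud = PointCloud(pts, (0.0, 0.0))
        out = trim_outliers(cloud, keep_frac=0.5)
        np.testing.assert_array_equal(out.points, [[1.0, 0.0], [0.0, 2.0]])

    def test_count_is_ceil(self):
        cloud = PointCloud(np.random.default_rng(0).normal(size=(11, 2)), (0, 0))
        assert len(trim_outliers(cloud, 0.9)) == 10  # ceil(9.9)

    def test_empty_raises(self):
        with pytest.raises(EmptyParticleError):
            trim_outliers(PointCloud(np.zeros((0, 2)), (0, 0)))

    def test_center_not_recomputed(self):
        cloud = PointCloud([[5.0, 0], [6.0, 0], [40.0, 0]], (0.0, 0.0))
        out = trim_outliers(cloud, 0.7)
        assert out.center == (0.0, 0.0)


class TestWrappedAngleDiff:
    def test_identical_angles(self):
        assert wrapped_angle_diff(1.234, 1.234) == 0.0

    def test_wrap_positive(self):
        assert wrapped_angle_diff(0.1, 2 * np.pi - 0.1) == pytest.approx(0.2)

    def test_wrap_negative(self):
        assert wrapped_angle_diff(np.pi + 0.1, 0.0) == pytest.approx(-(np.pi - 0.1))

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=200)
    def test_range_and_antisymmetry(self, a, b):
        d = wrapped_angle_diff(a, b)
        assert -np.pi < d <= np.pi
        d_rev = wrapped_angle_diff(b, a)
        if abs(d) != pytest.approx(np.pi):
            assert d_rev == pytest.approx(-d, abs=1e-9)


class TestEstimateOrientation:
    def test_ideal_corners_give_zero(self):
        est = estimate_orientation(_ideal_cloud(rotation=0.0), s=8)
        # zero modulo the symmetry period (float rounding may wrap to 2*pi/8)
        d = wrapped_angle_diff(8 * est.theta_star, 0.0) / 8
        assert abs(d) < 1e-9

    @pytest.mark.parametrize("rotation", [0.05, 0.2, 0.37])
    @pytest.mark.parametrize("method", ["closed_form", "grid_search"])
    def test_recovers_known_rotation(self, rotation, method):
        est = estimate_orientation(_ideal_cloud(rotation=rotation), s=8, method=method)
        assert est.theta_star == pytest.approx(rotation % (np.pi / 4), abs=2e-3)

    def test_noisefree_simulated_particle(self, rng):
        params = synthdata.NPCSimParams(
            p_label=1.0, points_per_corner=30, loc_noise_sd=0.0, rotation=0.61)
        cloud, truth = synthdata.gen_npc_pointcloud(params, rng=rng)
        est = estimate_orientation(cloud, s=8)
        assert est.theta_star == pytest.approx(truth["rotation"] % (np.pi / 4),
                                               abs=1e-6)

    def test_degenerate_cloud_flagged(self):
        # two points whose 8-folded angles are pi apart: resultant cancels
        pts = np.array([[1.0, 0.0],
                        [np.cos(np.pi / 8), np.sin(np.pi / 8)]])
        cloud = PointCloud(pts, (0.0, 0.0))
        with pytest.warns(UserWarning, match="orientation undefined"):
            est = estimate_orientation(cloud, s=8)
        assert est.degenerate
        assert est.theta_star == 0.0

    def test_empty_raises(self):
        with pytest.raises(EmptyParticleError):
            estimate_orientation(PointCloud(np.zeros((0, 2)), (0, 0)))

    def test_orientation_equivariance(self, rng):
        params = synthdata.NPCSimParams(
            p_label=0.9, points_per_corner=20, loc_noise_sd=3.0, rotation=0.1)
        cloud, _ = synthdata.gen_npc_pointcloud(params, rng=rng)
        base = estimate_orientation(cloud, s=8).theta_star
        delta = 0.17
        c, s_ = np.cos(delta), np.sin(delta)
        rot = cloud.points @ np.array([[c, s_], [-s_, c]])
        est = estimate_orientation(PointCloud(rot, (0, 0)), s=8)
        d = wrapped_angle_diff(8 * est.theta_star, 8 * (base + delta)) / 8
        assert abs(d) < 2e-3


class TestAssignSectors:
    def test_border_point_belongs_to_sector_it_opens(self):
        # theta*=0, s=8: borders at -pi/8 + k*pi/4. A point exactly at
        # angle pi/8 is the lower border of sector 1 (half-open convention).
        from exmquant.npc_symmetry import OrientationEstimate

        cloud = PointCloud([[np.cos(np.pi / 8), np.sin(np.pi / 8)]], (0, 0))
        est = OrientationEstimate(0.0, 8, 0.0, "closed_form")
        part = assign_sectors(cloud, est)
        assert part.sector_of_point[0] == 1

    def test_noise_free_particle_one_corner_per_sector(self):
        cloud = _ideal_cloud(n_per_corner=7, rotation=0.11)
        est = estimate_orientation(cloud, s=8)
        part = assign_sectors(cloud, est)
        np.testing.assert_array_equal(part.per_sector_counts, [7] * 8)

    def test_counts_conserved(self, rng):
        for _ in range(20):
            params = synthdata.NPCSimParams(
                p_label=0.8, points_per_corner=15, loc_noise_sd=5.0)
            cloud, _ = synthdata.gen_npc_pointcloud(params, rng=rng)
            if len(cloud) == 0:
                continue
            part = assign_sectors(cloud, estimate_orientation(cloud))
            assert part.per_sector_counts.sum() == len(cloud)

    def test_rotation_gives_cyclic_relabeling(self, rng):
        params = synthdata.NPCSimParams(
            p_label=0.7, points_per_corner=20, loc_noise_sd=2.0, rotation=0.05)
        cloud, _ = synthdata.gen_npc_pointcloud(params, rng=rng)
        part0 = assign_sectors(cloud, estimate_orientation(cloud))
        delta = 3 * np.pi / 4  # rotate by 3 sectors exactly
        c, s_ = np.cos(delta), np.sin(delta)
        rot = cloud.points @ np.array([[c, s_], [-s_, c]])
        cloud_r = PointCloud(rot, (0, 0))
        part1 = assign_sectors(cloud_r, estimate_orientation(cloud_r))
        counts0 = part0.per_sector_counts
        counts1 = part1.per_sector_counts
        assert any(
            np.array_equal(np.roll(counts0, k), counts1) for k in range(8)
        )


class TestCountActiveCorners:
    def test_zero_threshold_counts_nonempty_sectors(self):
        cloud = _ideal_cloud()
        part = assign_sectors(cloud, estimate_orientation(cloud))
        assert count_active_corners(part, activation_frac=0.0) == 8

    def test_full_labeling_noise_free_gives_8(self, rng):
        params = synthdata.NPCSimParams(p_label=1.0, points_per_corner=20,
                                        loc_noise_sd=0.0)
        cloud, _ = synthdata.gen_npc_pointcloud(params, rng=rng)
        # keep_frac=1: with zero noise every radius ties, so any trimming
        # rule would drop a whole corner's tail arbitrarily
        det = detect_corners(cloud, keep_frac=1.0)
        assert det.active_corners == 8

    def test_small_sector_inactive_at_strict_threshold(self):
        # one corner holds 4/100 points: inactive at activation_frac 0.05
        ang = 2 * np.pi * np.arange(8) / 8
        pts = []
        counts = [4, 14, 14, 14, 14, 14, 13, 13]  # total 100
        for k, n in enumerate(counts):
            pts.extend([[50 * np.cos(ang[k]), 50 * np.sin(ang[k])]] * n)
        cloud = PointCloud(np.array(pts), (0, 0))
        part = assign_sectors(cloud, estimate_orientation(cloud))
        active = count_active_corners(part, activation_frac=0.05)
        assert active == 7

    def test_strict_inequality(self):
        cloud = _ideal_cloud(n_per_corner=10)  # each sector holds exactly 1/8
        part = assign_sectors(cloud, estimate_orientation(cloud))
        assert count_active_corners(part, activation_frac=1 / 8) == 0


class TestRigidMotionInvariance:
    def test_translation_invariance(self, rng):
        params = synthdata.NPCSimParams(p_label=0.8, points_per_corner=20,
                                        loc_noise_sd=4.0)
        cloud, _ = synthdata.gen_npc_pointcloud(params, rng=rng)
        det0 = detect_corners(cloud)
        shifted = PointCloud(cloud.points + [123.0, -45.0],
                             (cloud.center[0] + 123.0, cloud.center[1] - 45.0))
        assert detect_corners(shifted).active_corners == det0.active_corners

    def test_rotation_invariance(self, rng):
        params = synthdata.NPCSimParams(p_label=0.8, points_per_corner=20,
                                        loc_noise_sd=4.0, rotation=0.07)
        cloud, _ = synthdata.gen_npc_pointcloud(params, rng=rng)
        det0 = detect_corners(cloud)
        delta = 0.9
        c, s_ = np.cos(delta), np.sin(delta)
        rot = cloud.points @ np.array([[c, s_], [-s_, c]])
        assert detect_corners(PointCloud(rot, (0, 0))).active_corners \
            == det0.active_corners


class TestCornerHistogram:
    def test_counts_and_mode(self):
        hist = corner_histogram([7, 7, 8, 6, 7], s=8, fit=False)
        assert hist.n_particles == 5
        assert hist.counts.sum() == 5
        assert hist.mode == 7

    def test_degenerate_histogram_fit_undefined(self):
        hist = corner_histogram([8] * 50, s=8)
        assert not hist.fit_defined

    def test_fit_recovers_discretized_gaussian(self, rng):
        # sample 10000 counts from a discretized Gaussian(mu=7, sigma=1)
        k = np.arange(9)
        p = np.exp(-((k - 7.0) ** 2) / 2.0)
        p /= p.sum()
        draws = rng.choice(k, size=10_000, p=p)
        hist = corner_histogram(draws.tolist(), s=8)
        assert hist.fit_defined
        assert hist.gauss_mu == pytest.approx(7.0, abs=0.1)
        assert hist.r_squared > 0.9

    def test_fit_r_squared_high_on_cohort(self, rng):
        params = synthdata.NPCSimParams(p_label=0.8, points_per_corner=20,
                                        loc_noise_sd=5.0)
        dets = []
        for cloud, _ in synthdata.gen_npc_cohort(params, 500, rng=rng):
            dets.append(detect_corners(cloud).active_corners if len(cloud) else 0)
        hist = corner_histogram(dets, s=8)
        assert hist.mode == 7
        assert hist.fit_defined


class TestEndToEndBinomial:
    def test_detected_distribution_matches_binomial(self, rng):
        import scipy.stats

        p_label = 0.8
        params = synthdata.NPCSimParams(p_label=p_label, points_per_corner=20,
                                        loc_noise_sd=5.0)
        dets, labs = [], []
        for cloud, truth in synthdata.gen_npc_cohort(params, 1500, rng=rng):
            labs.append(int(truth["labeled"].sum()))
            dets.append(detect_corners(cloud).active_corners if len(cloud) else 0)
        dets = np.array(dets)
        p_eff = dets.mean() / 8
        # detection can only lose corners at strict thresholds, so p_eff is
        # bounded above by the realized labeled fraction of this cohort
        assert p_label - 0.05 <= p_eff <= np.mean(labs) / 8 + 1e-12
        counts = np.bincount(dets, minlength=9)
        expected = scipy.stats.binom.pmf(np.arange(9), 8, p_eff) * dets.size
        keep = expected > 1.0
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        dof = keep.sum() - 2  # fitted p_eff + normalization
        p_value = scipy.stats.chi2.sf(chi2, dof)
        assert p_value > 0.01
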