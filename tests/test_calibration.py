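import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lvmotion.calibration import (
    CalibrationParams,
    CalibrationResult,
    ConeParams,
    PhantomModel,
    calibrate_frame,
    cluster_structures,
    combined_sigma,
    consistency_stats,
    fit_rigid,
    icp_refine,
    marker_registration,
    mask_cone,
    prealign_phantom,
    segment_edges,
    select_consistent,
)
from lvmotion.geometry import (
    HomogeneousTransform,
    PointCloud,
    compose,
    interpolate_pose,
    invert,
)
from lvmotion.synthetic import _fibonacci_sphere
from conftest import random_rigid


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentEdges:
    def test_uniform_volume_is_empty(self):
        assert len(segment_edges(np.full((20, 20, 20), 7.0))) == 0

    def test_sphere_edges_lie_on_surface(self):
        n = 48
        centre, radius = np.array([24.0, 24.0, 24.0]), 12.0
        ii, jj, kk = np.meshgrid(*[np.arange(n, dtype=float)] * 3, indexing="ij")
        r = np.sqrt((ii - centre[0]) ** 2 + (jj - centre[1]) ** 2 + (kk - centre[2]) ** 2)
        vol = np.where(r <= radius, 200.0, 20.0)
        edges = segment_edges(vol, sigma=1.5)
        assert len(edges) > 100
        # analytic surface-distance oracle
        dist = np.abs(np.linalg.norm(edges.points - centre, axis=1) - radius)
        assert np.all(dist <= 2.0)

    def test_axis_step_forms_plane(self):
        vol = np.full((30, 30, 10), 10.0)
        vol[15:, :, :] = 200.0
        edges = segment_edges(vol, sigma=1.0)
        assert len(edges) > 0
        assert np.all(np.abs(edges.points[:, 0] - 14.5) <= 1.5)

    def test_non_3d_rejected(self):
        with pytest.raises(ValueError):
            segment_edges(np.zeros((5, 5)))


class TestMaskCone:
    CONE = ConeParams(apex=(0, 0, 0), axis=(0, 0, 1), half_angle_deg=30, r_min=5, r_max=50)

    def test_axis_point_kept(self):
        out = mask_cone(PointCloud([[0, 0, 20.0]], "us"), self.CONE)
        assert len(out) == 1

    def test_point_behind_apex_removed(self):
        out = mask_cone(PointCloud([[0, 0, -20.0]], "us"), self.CONE)
        assert len(out) == 0

    def test_matches_per_point_oracle(self, rng):
        pts = rng.uniform(-60, 60, size=(500, 3))
        out = mask_cone(PointCloud(pts, "us"), self.CONE, margin=2.0)
        kept = {tuple(p) for p in out.points}
        half = np.deg2rad(30)
        for p in pts:
            r = np.linalg.norm(p)
            ang = np.arccos(np.clip(p[2] / r, -1, 1)) if r > 0 else 0.0
            inside = (
                5 + 2 <= r <= 50 - 2
                and ang <= half
                and r * np.sin(max(half - ang, 0.0)) >= 2.0
            )
            assert (tuple(p) in kept) == inside


class TestClusterStructures:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(scale=1.0, size=(100, 3))
        b = rng.normal(scale=1.0, size=(100, 3)) + [50, 0, 0]
        clusters = cluster_structures(PointCloud(np.vstack([a, b]), "us"), eps=5.0)
        assert len(clusters) == 2

    def test_tight_cloud_is_one_cluster(self, rng):
        pts = rng.uniform(0, 1.0, size=(80, 3))
        clusters = cluster_structures(PointCloud(pts, "us"), eps=3.0, size_floor=10)
        assert len(clusters) == 1

    def test_isolated_point_is_noise(self, rng):
        pts = np.vstack([rng.normal(size=(100, 3)), [[100.0, 100, 100]]])
        clusters = cluster_structures(PointCloud(pts, "us"), eps=3.0, min_pts=5)
        assert sum(len(c) for c in clusters) == 100


# ---------------------------------------------------------------------------
# rigid fits, pre-alignment and ICP
# ---------------------------------------------------------------------------

def _phantom_model():
    centres = np.array([(-20.0, -10, -5), (15, -15, 5), (5, 20, 12), (-8, 6, 22)])
    radii = np.array([5.0, 7, 9, 4])
    clouds = [c + r * _fibonacci_sphere(300) for c, r in zip(centres, radii)]
    cloud = PointCloud(np.concatenate(clouds), "phantom_ct", "structures")
    markers = {f"m{i}": p for i, p in enumerate(
        np.array([(-40.0, -40, -30), (45, -35, -25), (40, 40, 35), (-35, 45, 20)])
    )}
    return PhantomModel(structure_cloud=cloud, markers_ct=markers)


class TestPrealign:
    def test_self_alignment_is_identity(self):
        model = _phantom_model()
        src = PointCloud(model.structure_cloud.points.copy(), "us")
        t = prealign_phantom([src], model)
        assert np.allclose(t.matrix, np.eye(4), atol=1e-6)

    def test_translation_recovered(self):
        model = _phantom_model()
        src = PointCloud(model.structure_cloud.points - [10.0, 5.0, 0.0], "us")
        t = prealign_phantom([src], model)
        assert np.allclose(t.translation, [10.0, 5.0, 0.0], atol=1e-6)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-6)

    def test_random_rigid_recovered_to_fraction_of_diameter(self, rng):
        model = _phantom_model()
        tgt = model.structure_cloud.points
        diam = np.max(np.linalg.norm(tgt - tgt.mean(0), axis=1)) * 2
        for _ in range(5):
            motion = random_rigid(rng, max_angle_deg=90, max_trans=30)
            src = PointCloud(
                (tgt - motion.translation) @ motion.rotation, "us"
            )  # inverse motion applied
            t = prealign_phantom([src], model)
            from lvmotion.calibration import _directed_hd

            hd = _directed_hd(t.apply(src.points), tgt)
            assert hd < 0.1 * diam

    def test_degenerate_cloud_rejected(self):
        model = _phantom_model()
        line = PointCloud(np.outer(np.linspace(0, 1, 60), [1.0, 0, 0]), "us")
        with pytest.raises(ValueError):
            prealign_phantom([line], model)


class TestIcp:
    def test_identity_on_identical_clouds(self):
        model = _phantom_model()
        src = PointCloud(model.structure_cloud.points.copy(), "us")
        init = HomogeneousTransform(np.eye(4), "us", "phantom_ct")
        t, hd, converged = icp_refine(src, model.structure_cloud, init)
        assert converged
        assert hd < 1e-9
        assert np.allclose(t.matrix, np.eye(4), atol=1e-9)

    def test_known_rigid_motion_recovered(self, rng):
        model = _phantom_model()
        tgt = model.structure_cloud
        motion = random_rigid(rng, max_angle_deg=45, max_trans=20)
        src = PointCloud(invert(
            HomogeneousTransform(motion.matrix, "us", "phantom_ct")
        ).apply(tgt.points), "us")
        # init within ~5 deg / 5 mm of the truth
        bump = Rotation.from_rotvec(np.deg2rad(5) * np.array([1.0, 0, 0]))
        init_m = motion.matrix.copy()
        init_m[:3, :3] = bump.as_matrix() @ init_m[:3, :3]
        init_m[:3, 3] += [3.0, -2.0, 4.0]
        init = HomogeneousTransform(init_m, "us", "phantom_ct")
        t, hd, _ = icp_refine(src, tgt, init)
        assert hd < 1e-3
        assert np.allclose(t.matrix, motion.matrix, atol=1e-3)

    def test_flipped_init_yields_high_flagged_residual(self):
        model = _phantom_model()
        src = PointCloud(model.structure_cloud.points.copy(), "us")
        flip = np.diag([1.0, -1.0, -1.0])  # 180 deg flip
        init = HomogeneousTransform.from_rotation_translation(
            flip, (60.0, 0, 0), "us", "phantom_ct"
        )
        _, hd, _ = icp_refine(src, model.structure_cloud, init, max_iter=30)
        assert hd > 5.0  # the Fig.-style failure: registration stuck far away

    def test_empty_cloud_rejected(self):
        model = _phantom_model()
        with pytest.raises(ValueError):
            icp_refine(
                PointCloud(np.empty((0, 3)), "us"),
                model.structure_cloud,
                HomogeneousTransform(np.eye(4), "us", "phantom_ct"),
            )


class TestMarkerRegistration:
    MARKERS = np.array([(-40.0, -40, -30), (45, -35, -25), (40, 40, 35), (-35, 45, 20)])

    def test_identity(self):
        t, rms = marker_registration(self.MARKERS, self.MARKERS)
        assert np.allclose(t.matrix, np.eye(4), atol=1e-9)
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_exact(self):
        t, rms = marker_registration(self.MARKERS, self.MARKERS + [3.0, -1.0, 2.0])
        assert np.allclose(t.translation, [3.0, -1.0, 2.0], atol=1e-9)
        assert rms < 1e-9

    def test_noisy_rigid_recovered(self, rng):
        motion = random_rigid(rng, max_angle_deg=60, max_trans=100)
        moved = self.MARKERS @ motion.rotation.T + motion.translation
        moved += rng.normal(scale=0.1, size=moved.shape)
        t, rms = marker_registration(self.MARKERS, moved)
        assert np.linalg.norm(t.translation - motion.translation) < 0.5
        dr = Rotation.from_matrix(t.rotation @ motion.rotation.T)
        assert np.rad2deg(np.linalg.norm(dr.as_rotvec())) < 0.5
        assert rms < 0.5

    def test_collinear_rejected(self):
        line = np.outer([0.0, 1, 2], [1.0, 0, 0])
        with pytest.raises(ValueError):
            marker_registration(line, line)

    def test_fit_rigid_returns_proper_rotation(self, rng):
        a = rng.normal(size=(10, 3))
        b = -a  # a reflection would fit perfectly; must be rejected
        r, _ = fit_rigid(a, b)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# per-frame calibration and consistency
# ---------------------------------------------------------------------------

class TestCalibrateFrame:
    def test_recovers_ground_truth_on_rendered_frame(self, small_world):
        w = small_world
        params = CalibrationParams(cone=w.config.cone)
        t = float(w.cal_frame_times[0])
        vol = w.render_frame(t, "cal")
        pose = interpolate_pose(w.cal_tracking, t)
        res = calibrate_frame(vol, w.us_geom, pose, w.phantom, params)
        assert not res.failed
        err = compose(invert(w.true_t_pr_us), res.t_pr_us)
        assert np.linalg.norm(err.translation) < 1.0
        ang = np.rad2deg(np.linalg.norm(Rotation.from_matrix(err.rotation).as_rotvec()))
        assert ang < 1.0

    def test_composition_equals_factor_product(self, small_world):
        w = small_world
        params = CalibrationParams(cone=w.config.cone)
        t = float(w.cal_frame_times[1])
        pose = interpolate_pose(w.cal_tracking, t)
        res = calibrate_frame(w.render_frame(t, "cal"), w.us_geom, pose, w.phantom, params)
        product = res.t_pr_tr.matrix @ res.t_tr_ct.matrix @ res.t_ct_us.matrix
        assert np.allclose(res.t_pr_us.matrix, product, atol=1e-9)

    def test_blank_frame_fails_with_stage(self, small_world):
        w = small_world
        params = CalibrationParams(cone=w.config.cone)
        pose = interpolate_pose(w.cal_tracking, float(w.cal_frame_times[0]))
        res = calibrate_frame(
            np.zeros(w.us_geom.size, dtype=float), w.us_geom, pose, w.phantom, params
        )
        assert res.failed
        assert res.failed_stage == "segment_edges"


def _result(i, hd):
    ident = HomogeneousTransform.identity("us")
    return CalibrationResult(ident, ident, ident, ident, hd, i)


class TestSelectConsistent:
    def test_smallest_k_kept(self, rng):
        hds = rng.permutation(100).astype(float)
        results = [_result(i, h) for i, h in enumerate(hds)]
        kept = select_consistent(results, k=30)
        assert sorted(r.residual_hd for r in kept) == sorted(hds)[:30]

    def test_keep_all_when_k_equals_len(self):
        results = [_result(i, float(i)) for i in range(5)]
        assert len(select_consistent(results, k=5)) == 5

    def test_tie_at_cut_prefers_lower_frame(self):
        results = [_result(0, 1.0), _result(1, 2.0), _result(2, 2.0)]
        kept = select_consistent(results, k=2)
        assert [r.frame_index for r in kept] == [0, 1]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_consistent([_result(0, 1.0)], k=2)


class TestConsistencyStats:
    def _random_results(self, rng, n=10):
        out = []
        for i in range(n):
            t = random_rigid(rng, max_angle_deg=5, max_trans=2)
            out.append(
                CalibrationResult(
                    HomogeneousTransform(t.matrix, "us", "probe"),
                    t, t, t, float(i), i,
                )
            )
        return out

    def test_identical_transforms_have_zero_spread(self, rng):
        t = random_rigid(rng)
        r = CalibrationResult(HomogeneousTransform(t.matrix, "us", "probe"), t, t, t, 0.0, 0)
        pts = PointCloud(rng.uniform(-40, 40, (10, 3)), "us")
        report = consistency_stats([r, r, r], pts)
        assert np.allclose(report.sigma, 0.0)
        assert np.allclose(report.combined, 0.0)

    def test_permutation_invariant(self, rng):
        results = self._random_results(rng)
        pts = PointCloud(rng.uniform(-40, 40, (10, 3)), "us")
        a = consistency_stats(results, pts)
        b = consistency_stats(results[::-1], pts)
        assert np.allclose(a.combined, b.combined, atol=1e-12)

    def test_combined_is_root_sum_of_squares(self, rng):
        results = self._random_results(rng)
        pts = PointCloud(rng.uniform(-40, 40, (5, 3)), "us")
        report = consistency_stats(results, pts)
        assert np.allclose(
            report.combined, np.sqrt(np.sum(report.sigma**2, axis=1)), atol=1e-9
        )


class TestCombinedSigma:
    @pytest.mark.parametrize(
        "sigma, expected",
        [((1.9, 2.6, 3.8), 5.0), ((1.1, 1.2, 2.9), 3.3), ((1.3, 1.4, 2.8), 3.4)],
    )
    def test_reported_combined_values(self, sigma, expected):
        assert round(float(combined_sigma(np.array(sigma))[0]), 1) == expected
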