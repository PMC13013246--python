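import numpy as np
import pytest
from scipy.spatial.distance import directed_hausdorff as scipy_dhd

from lvmotion.evaluation import (
    SegmentModel,
    assign_segments,
    bullseye,
    dice,
    directed_hausdorff,
    hd95,
    point_displacements,
)
from lvmotion.geometry import PointCloud


def _brute_nn(a, b):
    return np.array([np.min(np.linalg.norm(b - p, axis=1)) for p in a])


class TestDirectedHausdorff:
    def test_identical_clouds(self, rng):
        pts = rng.normal(size=(50, 3))
        assert directed_hausdorff(pts, pts) == 0.0

    def test_three_four_five(self):
        assert directed_hausdorff(np.array([[0.0, 0, 0]]), np.array([[3.0, 4, 0]])) == 5.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            a = rng.normal(size=(200, 3))
            b = rng.normal(size=(150, 3))
            assert directed_hausdorff(a, b) == pytest.approx(
                float(np.max(_brute_nn(a, b))), abs=1e-12
            )

    def test_asymmetric_but_bidirectional_matches_scipy(self, rng):
        a = rng.normal(size=(80, 3))
        b = rng.normal(size=(60, 3)) + 0.5
        ours = max(directed_hausdorff(a, b), directed_hausdorff(b, a))
        ref = max(scipy_dhd(a, b)[0], scipy_dhd(b, a)[0])
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            directed_hausdorff(np.empty((0, 3)), np.zeros((1, 3)))


class TestHd95:
    def test_identical_clouds(self, rng):
        pts = rng.normal(size=(30, 3))
        assert hd95(pts, pts) == 0.0

    def test_outlier_robustness(self):
        a = np.zeros((101, 3))
        a[:100, 0] = np.arange(100)
        a[:100, 1] = 1.0  # 100 points each exactly 1 away from the lattice
        a[100] = [0.0, 100.0, 0.0]  # one far outlier
        b = np.column_stack([np.arange(100.0), np.zeros(100), np.zeros(100)])
        assert hd95(a, b) == pytest.approx(1.0)

    def test_matches_percentile_oracle(self, rng):
        for _ in range(5):
            a = rng.normal(size=(120, 3))
            b = rng.normal(size=(90, 3))
            oracle = float(np.percentile(_brute_nn(a, b), 95))
            assert hd95(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_never_exceeds_directed_hausdorff(self, rng):
        for _ in range(10):
            a = rng.normal(size=(60, 3))
            b = rng.normal(size=(60, 3))
            assert hd95(a, b) <= directed_hausdorff(a, b) + 1e-12


class TestDice:
    def test_identical_inputs(self, rng):
        pts = rng.uniform(0, 10, size=(300, 3))
        assert dice(pts, pts) == 1.0

    def test_disjoint_inputs(self, rng):
        a = rng.uniform(0, 5, size=(100, 3))
        assert dice(a, a + 100.0) == 0.0

    def test_overlapping_cubes_analytic(self):
        # unit-spaced voxel-centre grids: A covers x in 0..3, B covers x in 2..5
        g = np.stack(np.meshgrid(*[np.arange(4) + 0.5] * 3, indexing="ij"), -1).reshape(-1, 3)
        a = g.copy()
        b = g.copy()
        b[:, 0] += 2.0
        # |A| = |B| = 64 voxels, overlap 2x4x4 = 32
        assert dice(a, b, grid_spacing=1.0) == pytest.approx(2 * 32 / 128)

    def test_invariant_under_common_shift(self, rng):
        a = rng.uniform(0, 10, size=(200, 3))
        b = rng.uniform(0, 10, size=(200, 3))
        d0 = dice(a, b)
        shift = np.array([7.0, -3.0, 11.0])  # multiple of the 1 mm grid
        assert dice(a + shift, b + shift) == pytest.approx(d0)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            dice(np.empty((0, 3)), np.empty((0, 3)))


class TestPointDisplacements:
    def test_subset_gives_zeros(self, rng):
        b = rng.normal(size=(100, 3))
        assert np.allclose(point_displacements(b[:20], b), 0.0)

    def test_plane_offset(self):
        plane = np.stack(np.meshgrid(np.arange(10), np.arange(10), [0.0]), -1).reshape(-1, 3)
        assert point_displacements(np.array([[5.0, 5.0, 7.0]]), plane)[0] == pytest.approx(7.0)

    def test_matches_brute_force(self, rng):
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(70, 3))
        assert np.allclose(point_displacements(a, b), _brute_nn(a, b), atol=1e-12)


def _model():
    return SegmentModel(
        apex=np.array([0.0, 0.0, -35.0]),
        mitral_centre=np.array([0.0, 0.0, 30.0]),
        aortic_centre=np.array([-10.0, 6.0, 28.0]),
    )


def _oracle_assign(p, model):
    """Independent per-point classifier following the same convention."""
    rel = p - model.apex
    s = rel @ model.long_axis / model.axis_length
    if s < model.cap_fraction:
        return 17
    third = (1 - model.cap_fraction) / 3
    theta = np.arctan2(rel @ model.ortho, rel @ model.angular_reference)
    if s < model.cap_fraction + third:
        n, base = 4, 13
    elif s < model.cap_fraction + 2 * third:
        n, base = 6, 7
    else:
        n, base = 6, 1
    width = 2 * np.pi / n
    sec = int(np.floor((theta + width / 2) / width)) % n
    return base + (sec + 1) % n


class TestAssignSegments:
    def test_apex_is_cap(self):
        m = _model()
        assert assign_segments(np.array([[0.0, 0.0, -35.0]]), m)[0] == 17

    def test_basal_aortic_direction_is_segment_two(self):
        m = _model()
        # basal-level point along the projected aortic direction
        centre = m.apex + 0.9 * m.axis_length * m.long_axis
        p = centre + 20.0 * m.angular_reference
        assert assign_segments(p[None, :], m)[0] == 2

    def test_partition_into_1_to_17(self, rng):
        m = _model()
        pts = rng.uniform(-30, 30, size=(2000, 3))
        seg = assign_segments(pts, m)
        assert seg.min() >= 1 and seg.max() <= 17
        assert len(seg) == len(pts)

    def test_matches_independent_classifier(self, rng):
        m = _model()
        u = rng.normal(size=(1500, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = np.array([0.0, 0.0, -2.5]) + u * np.array([20.0, 20.0, 32.0])
        seg = assign_segments(pts, m)
        oracle = np.array([_oracle_assign(p, m) for p in pts])
        assert np.array_equal(seg, oracle)

    def test_all_rings_populated_on_dense_shell(self, rng):
        m = _model()
        u = rng.normal(size=(5000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = np.array([0.0, 0.0, -2.5]) + u * np.array([20.0, 20.0, 32.0])
        seg = set(assign_segments(pts, m))
        assert seg == set(range(1, 18))


class TestBullseye:
    def test_zero_displacements(self, rng):
        m = _model()
        u = rng.normal(size=(1000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = u * np.array([20.0, 20.0, 32.0]) - [0, 0, 2.5]
        seg_map = bullseye(pts, np.zeros(len(pts)), m)
        filled = ~np.isnan(seg_map.values)
        assert np.allclose(seg_map.values[filled], 0.0)

    def test_one_point_per_segment_forced_values(self, rng):
        m = _model()
        u = rng.normal(size=(4000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = u * np.array([20.0, 20.0, 32.0]) - [0, 0, 2.5]
        seg = assign_segments(pts, m)
        picks = [np.where(seg == i)[0][0] for i in range(1, 18)]
        chosen = pts[picks]
        seg_map = bullseye(chosen, np.arange(1.0, 18.0), m)
        assert np.allclose(seg_map.values, np.arange(1.0, 18.0))
        assert np.all(seg_map.counts == 1)

    def test_matches_groupby_max_oracle(self, rng):
        m = _model()
        pts = rng.uniform(-30, 30, size=(500, 3))
        disp = rng.uniform(0, 10, size=500)
        seg_map = bullseye(pts, disp, m)
        seg = assign_segments(pts, m)
        for i in range(1, 18):
            members = disp[seg == i]
            if len(members):
                assert seg_map.values[i - 1] == pytest.approx(members.max())
            else:
                assert np.isnan(seg_map.values[i - 1])
                assert i in seg_map.missing

    def test_empty_segment_flagged_not_zero(self):
        m = _model()
        p = np.array([[0.0, 0.0, -35.0]])  # only the cap
        seg_map = bullseye(p, np.array([2.0]), m)
        assert seg_map.values[16] == 2.0
        assert 1 in seg_map.missing
        assert np.isnan(seg_map.values[0])


class TestCrossTransferMatrix:
    def test_identity_world_matrix_and_diagonal_oracle(self, rng):
        from lvmotion.evaluation import cross_transfer_matrix
        from lvmotion.fusion import TransferChain, transfer_segmentation
        from lvmotion.geometry import HomogeneousTransform, TrackingStream, VolumeGeometry
        from lvmotion.registration import NormParams, RegistrationResult

        ident_pose = HomogeneousTransform(np.eye(4), "probe", "tracking")
        tracking = TrackingStream(np.array([0.0, 10.0]), [ident_pose, ident_pose])
        reg = RegistrationResult(
            prealign=HomogeneousTransform(np.eye(4), "us", "ct"),
            affine_b=np.eye(3), affine_t=np.zeros(3),
            norm_source=NormParams(np.zeros(3), 1.0),
            norm_target=NormParams(np.zeros(3), 1.0),
            sigma2=0.0, baseline_time=0.0,
            t_ust_tr=HomogeneousTransform(np.eye(4), "tracking", "probe"),
            landmark_residuals=np.zeros(3),
        )
        geom = VolumeGeometry.unit((6, 6, 6))
        chains = [
            TransferChain(
                geom=geom,
                calibration=HomogeneousTransform(np.eye(4), "us", "probe"),
                tracking=tracking,
                registration=reg,
            )
            for _ in range(3)
        ]
        segs = [(rng.uniform(size=(6, 6, 6)) > 0.5).astype(np.uint8) for _ in range(3)]
        ct = PointCloud(
            np.unique(np.vstack([np.argwhere(s > 0) for s in segs]), axis=0).astype(float),
            "ct",
        )
        times = np.array([0.5, 1.0, 1.5])
        mat = cross_transfer_matrix(times, segs, chains, ct)
        assert np.nanmax(mat) < 1e-9
        for j in range(3):
            direct = hd95(transfer_segmentation(chains[j], float(times[j]), segs[j]), ct)
            assert mat[j, j] == pytest.approx(direct, abs=1e-12)
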