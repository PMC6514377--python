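import numpy as np
import pytest

from phenolidar.cloud import PointCloud
from phenolidar.registration import (
    RegistrationError,
    RigidTransform,
    coarse_align,
    icp_refine,
    kabsch,
    merge_clouds,
    register_via_landmarks,
    select_plots,
)


def rot_z(deg):
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])


class TestRigidTransform:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]))  # reflection
        with pytest.raises(ValueError):
            RigidTransform(np.ones((3, 3)))

    def test_compose_inverse(self, rng):
        a = RigidTransform(rot_z(31.0), rng.normal(size=3))
        b = RigidTransform(rot_z(-12.0), rng.normal(size=3))
        pts = rng.normal(size=(20, 3))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)))
        assert np.allclose(a.compose(a.inverse()).apply(pts), pts, atol=1e-12)


class TestKabsch:
    def test_identity_and_pure_translation(self, rng):
        src = rng.normal(size=(10, 3))
        t = kabsch(src, src)
        assert np.allclose(t.R, np.eye(3), atol=1e-12)
        assert np.allclose(t.T, 0, atol=1e-12)
        t = kabsch(src, src + [1.0, 2.0, 3.0])
        assert np.allclose(t.R, np.eye(3), atol=1e-12)
        assert np.allclose(t.T, [1, 2, 3], atol=1e-12)

    def test_recovers_synthetic_rigid_motion_exactly(self, rng):
        src = rng.normal(size=(20, 3))
        R, T = rot_z(10.0), np.array([0.5, -1.0, 2.0])
        t = kabsch(src, src @ R.T + T)
        assert np.abs(t.R - R).max() <= 1e-9
        assert np.abs(t.T - T).max() <= 1e-9
        # rotation invariants hold to tight tolerance
        assert np.abs(t.R.T @ t.R - np.eye(3)).max() <= 1e-9
        assert abs(np.linalg.det(t.R) - 1) <= 1e-9

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line)
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


def _three_plate_virtual(offset=np.zeros(3)):
    from phenolidar.landmarks import LandmarkFilterParams, make_virtual_landmark

    plates = []
    for y0 in (0.0, 2.3, 5.1):
        corner = np.array([2.7, y0, 1.1]) + offset
        plates.append(make_virtual_landmark(corner, LandmarkFilterParams(), 0.02, 0.02).points)
    return PointCloud(np.vstack(plates))


class TestCoarseAlign:
    def test_identity_case(self):
        vl = _three_plate_virtual()
        t = coarse_align(vl, vl, feature_radius=0.06, seed=0)
        moved = t.apply(vl.points)
        # residual against the target is essentially zero
        from scipy.spatial import cKDTree

        d, _ = cKDTree(vl.points).query(moved)
        assert np.sqrt((d**2).mean()) <= 0.02

    def test_recovers_offset_between_plate_sets(self):
        src = _three_plate_virtual()
        dst = _three_plate_virtual(offset=np.array([0.0, 1.0, 0.0]))
        t = coarse_align(src, dst, feature_radius=0.06, seed=0)
        assert np.linalg.norm(t.T - [0, 1, 0]) <= 0.05
        assert t.rotation_angle_deg() <= 2.0

    def test_deterministic_given_seed(self):
        src = _three_plate_virtual()
        dst = _three_plate_virtual(offset=np.array([0.0, 1.0, 0.0]))
        t1 = coarse_align(src, dst, feature_radius=0.06, seed=7)
        t2 = coarse_align(src, dst, feature_radius=0.06, seed=7)
        assert np.array_equal(t1.R, t2.R) and np.array_equal(t1.T, t2.T)

    def test_empty_cloud_rejected(self):
        with pytest.raises(RegistrationError):
            coarse_align(PointCloud(), _three_plate_virtual())


class TestIcp:
    def test_converges_immediately_from_truth(self, rng):
        pts = rng.normal(size=(200, 3))
        src = PointCloud(pts)
        truth = RigidTransform(rot_z(3.0), np.array([0.2, -0.1, 0.05]))
        dst = PointCloud(truth.apply(pts))
        res = icp_refine(src, dst, truth, tol=1e-6)
        assert res.converged and res.n_iterations <= 2
        assert res.rms_residual <= 1e-6

    def test_recovers_pose_under_sensor_noise(self, rng):
        pts = rng.uniform(0, 2, (500, 3))
        truth = RigidTransform(np.eye(3), np.array([0.15, -0.1, 0.05]))
        dst = PointCloud(truth.apply(pts) + rng.normal(0, 0.02, (500, 3)))
        res = icp_refine(PointCloud(pts), dst, RigidTransform(), max_iter=100)
        assert np.linalg.norm(res.transform.T - truth.T) <= 0.03

    def test_residual_monotone_non_increasing(self, rng):
        """The per-iteration RMS never increases, whatever the input."""
        from scipy.spatial import cKDTree

        pts = rng.uniform(0, 1, (300, 3))
        dst = PointCloud(rng.uniform(0, 1, (300, 3)))
        tree = cKDTree(dst.points)
        t = RigidTransform()
        prev = np.inf
        for _ in range(10):
            d, idx = tree.query(t.apply(pts))
            rms = np.sqrt((d**2).mean())
            assert rms <= prev + 1e-12
            prev = rms
            res = icp_refine(PointCloud(pts), dst, t, max_iter=1, tol=0.0)
            t = res.transform

    def test_final_not_worse_than_initial(self, rng):
        from scipy.spatial import cKDTree

        pts = rng.uniform(0, 1, (200, 3))
        dst = PointCloud(rng.uniform(0, 1, (250, 3)))
        init = RigidTransform(rot_z(5.0), np.array([0.3, 0, 0]))
        res = icp_refine(PointCloud(pts), dst, init)
        tree = cKDTree(dst.points)
        d0, _ = tree.query(init.apply(pts))
        assert res.rms_residual <= np.sqrt((d0**2).mean()) + 1e-12

    def test_empty_inputs_rejected(self):
        with pytest.raises(RegistrationError):
            icp_refine(PointCloud(), PointCloud(np.zeros((3, 3))))


class TestRegisterViaLandmarks:
    def test_identical_scans_give_identity(self, rng):
        plates = [
            np.column_stack([
                np.full(120, 2.7),
                rng.uniform(y0, y0 + 0.4, 120),
                rng.uniform(0.8, 1.1, 120),
            ])
            for y0 in (0.0, 2.3, 5.1, 7.2)
        ]
        ground = rng.uniform([0, -1, -1.2], [10, 8, -1.1], (500, 3))
        scan = PointCloud(np.vstack(plates + [ground]))
        res = register_via_landmarks(scan, scan, canopy_cut_z=0.5, seed=0)
        assert res.transform.rotation_angle_deg() <= 0.1
        assert np.linalg.norm(res.transform.T) <= 0.01

    def test_no_landmarks_fails_with_diagnostic(self):
        flat = PointCloud(np.random.default_rng(0).uniform(0, 1, (100, 3)))
        with pytest.raises(RegistrationError, match="landmark"):
            register_via_landmarks(flat, flat, canopy_cut_z=5.0)


class TestMergeAndPlots:
    def test_single_cloud_identity_unchanged(self, rng):
        pts = rng.normal(size=(50, 3))
        out = merge_clouds([PointCloud(pts)], [RigidTransform()])
        assert np.allclose(out.points, pts)

    def test_point_count_conservation(self, rng):
        a, b = rng.normal(size=(100, 3)), rng.normal(size=(100, 3)) + 10
        out = merge_clouds(
            [PointCloud(a), PointCloud(b)], [RigidTransform(), RigidTransform()]
        )
        assert len(out) == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge_clouds([PointCloud(np.zeros((3, 3)))], [])

    @pytest.mark.parametrize("step,expected_n", [(1, 30), (2, 15), (3, 10)])
    def test_plot_selection_counts(self, step, expected_n):
        plots = select_plots(30, step)
        assert len(plots) == expected_n
        assert plots[0] == step and plots[-1] <= 30
        assert all(p % step == 0 for p in plots)

    def test_step_beyond_range_gives_single_plot(self):
        assert select_plots(5, 9) == [5]
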