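import numpy as np
import pytest
from sklearn.cluster import DBSCAN as SkDBSCAN

from phenolidar.cloud import PointCloud
from phenolidar.landmarks import (
    BORDER,
    CORE,
    NOISE,
    DbscanParams,
    LandmarkFilterParams,
    cut_above_canopy,
    dbscan,
    detect_landmarks,
    detection_success_rate,
    extract_corner,
    filter_landmark_candidates,
    make_virtual_landmark,
)


def same_partition(labels_a, labels_b):
    """Cluster labelings are identical up to renaming (noise = -1 fixed)."""
    if not np.array_equal(labels_a == -1, labels_b == -1):
        return False
    mapping = {}
    for a, b in zip(labels_a, labels_b):
        if a == -1:
            continue
        if mapping.setdefault(a, b) != b:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestDbscan:
    def test_core_border_noise_textbook_configuration(self):
        """Two dense cores within E of each other merge; a point hanging off
        one core is border; an isolated point is noise."""
        E, minpts = 1.0, 5
        p = np.array([0.0, 0, 0])
        q = np.array([1.0, 0, 0])
        p_ring = p + np.array([[0.3, 0.3, 0], [0.3, -0.3, 0], [0.3, 0, 0.3], [0.3, 0, -0.3]])
        q_ring = q + np.array([[-0.3, 0.3, 0], [-0.3, -0.3, 0], [-0.3, 0, 0.3], [-0.3, 0, -0.3]])
        b = np.array([1.95, 0, 0])
        n = np.array([5.0, 5, 5])
        pts = np.vstack([p, q, p_ring, q_ring, b, n])
        res = dbscan(PointCloud(pts), DbscanParams(E, minpts))
        assert res.point_type[0] == CORE and res.point_type[1] == CORE
        assert res.point_type[10] == BORDER
        assert res.point_type[11] == NOISE
        # density-reachable cores end up in one cluster together with b
        assert res.labels[0] == res.labels[1] == res.labels[10]
        assert res.labels[11] == -1

    def test_single_point_is_noise(self):
        res = dbscan(PointCloud([[0, 0, 0]]), DbscanParams(0.5, 5))
        assert res.labels.tolist() == [-1]
        assert res.point_type.tolist() == [NOISE]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_reference(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 3, (300, 3))
        params = DbscanParams(0.3, 4)
        ours = dbscan(PointCloud(pts), params)
        ref = SkDBSCAN(eps=params.E, min_samples=params.MinPts).fit(pts)
        assert same_partition(ours.labels, ref.labels_)
        ref_core = np.zeros(len(pts), dtype=bool)
        ref_core[ref.core_sample_indices_] = True
        assert np.array_equal(ours.point_type == CORE, ref_core)

    def test_pointwise_definitions_hold(self, rng):
        """CORE/BORDER/NOISE roles verified by direct neighbor counting."""
        pts = rng.uniform(0, 2, (200, 3))
        params = DbscanParams(0.35, 5)
        res = dbscan(PointCloud(pts), params)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        n_nb = (d <= params.E).sum(axis=1)
        core = n_nb >= params.MinPts
        for i in range(len(pts)):
            if res.point_type[i] == CORE:
                assert core[i]
            elif res.point_type[i] == BORDER:
                assert not core[i] and core[(d[i] <= params.E)].any()
            else:
                assert not core[i] and not core[(d[i] <= params.E)].any()

    def test_permutation_invariant_up_to_relabeling(self, rng):
        pts = rng.uniform(0, 2, (150, 3))
        params = DbscanParams(0.4, 4)
        res = dbscan(PointCloud(pts), params)
        perm = rng.permutation(len(pts))
        res_p = dbscan(PointCloud(pts[perm]), params)
        assert same_partition(res.labels[perm], res_p.labels)


class TestCanopyCut:
    def test_plate_survives_plants_removed(self, rng):
        plants = rng.uniform([0, 0, 0], [5, 5, 0.7], (500, 3))
        plate = rng.uniform([2, 2, 0.8], [2.4, 2.3, 1.1], (100, 3))
        cloud = PointCloud(np.vstack([plants, plate]))
        out = cut_above_canopy(cloud, 0.75)
        assert len(out) == 100 and out.points[:, 2].min() > 0.75

    def test_all_below_cut_empty(self):
        assert len(cut_above_canopy(PointCloud(np.zeros((10, 3))), 0.5)) == 0

    def test_matches_brute_force(self, rng):
        pts = rng.normal(size=(300, 3))
        out = cut_above_canopy(PointCloud(pts), 0.2)
        assert np.array_equal(out.points, pts[pts[:, 2] > 0.2])


class TestCornerAndVirtual:
    def test_axis_aligned_plate_corner(self):
        y, z = np.meshgrid(np.linspace(1.0, 1.4, 9), np.linspace(0.8, 1.1, 7))
        pts = np.column_stack([np.full(y.size, 2.0), y.ravel(), z.ravel()])
        assert np.allclose(extract_corner(pts), [2.0, 1.0, 1.1])

    def test_single_point_is_its_own_corner(self):
        assert np.allclose(extract_corner(np.array([[1.0, 2.0, 3.0]])), [1, 2, 3])

    def test_invariant_to_order_and_duplication(self, rng):
        pts = rng.uniform(0, 1, (50, 3))
        c = extract_corner(pts)
        assert np.allclose(extract_corner(pts[::-1]), c)
        assert np.allclose(extract_corner(np.vstack([pts, pts])), c)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            extract_corner(np.empty((0, 3)))

    def test_virtual_grid_counts(self):
        corner = np.array([2.0, 1.0, 1.1])
        p = LandmarkFilterParams()
        assert len(make_virtual_landmark(corner, p, 0.40, 0.30)) == 4
        assert len(make_virtual_landmark(corner, p, 0.01, 0.01)) == 41 * 31

    def test_virtual_grid_geometry(self):
        corner = np.array([2.0, 1.0, 1.1])
        vl = make_virtual_landmark(corner, LandmarkFilterParams(), 0.01, 0.01)
        assert vl.points[:, 1].min() == pytest.approx(1.0)
        assert vl.points[:, 2].max() == pytest.approx(1.1)
        assert np.allclose(vl.points[:, 0], 2.0)

    def test_degenerate_large_step_allowed(self):
        vl = make_virtual_landmark(np.zeros(3), LandmarkFilterParams(), 1.0, 1.0)
        assert len(vl) == 1


class TestFilteringAndDetection:
    def _cluster_fixture(self, clusters):
        pts = np.vstack(clusters)
        labels = np.concatenate([np.full(len(c), i) for i, c in enumerate(clusters)])
        from phenolidar.landmarks import ClusterResult

        return PointCloud(pts), ClusterResult(labels, np.full(len(pts), CORE))

    def test_vertical_extent_rule(self, rng):
        plate = rng.uniform([0, 0, 0.8], [0.02, 0.4, 1.1], (60, 3))
        flat = rng.uniform([3, 3, 0.8], [3.4, 3.4, 0.82], (60, 3))
        cloud, clusters = self._cluster_fixture([plate, flat])
        assert filter_landmark_candidates(clusters, cloud) == [0]

    def test_synthetic_scene_detects_exactly_the_plates(self, rng):
        """Five plates plus flat noise blobs above the canopy cut: detection
        returns one landmark per plate, with the expected upper corners."""
        plates, truth_corners = [], []
        for k in range(5):
            y0 = 2.0 * k
            pts = np.column_stack([
                np.full(150, 1.5 + 0.3 * k),
                rng.uniform(y0, y0 + 0.4, 150),
                rng.uniform(0.8, 1.1, 150),
            ])
            plates.append(pts)
            truth_corners.append([1.5 + 0.3 * k, y0, 1.1])
        blobs = [
            rng.uniform([x, y, 0.76], [x + 0.3, y + 0.3, 0.79], (30, 3))
            for x, y in [(4, 1), (5, 3), (6, 5), (4.5, 7), (5.5, 9),
                         (7, 0), (7, 2), (7, 4), (7, 6), (7, 8),
                         (8.5, 1), (8.5, 3), (8.5, 5), (8.5, 7), (8.5, 9),
                         (10, 0.5), (10, 2.5), (10, 4.5), (10, 6.5), (10, 8.5)]
        ]
        scan = PointCloud(np.vstack(plates + blobs))
        dets = detect_landmarks(scan, canopy_cut_z=0.75)
        assert len(dets) == 5
        for det, truth in zip(dets, sorted(truth_corners, key=lambda c: c[1])):
            assert np.linalg.norm(det.corner - truth) <= 0.05

    def test_empty_scene_gives_empty_list(self):
        assert detect_landmarks(PointCloud(np.zeros((50, 3))), 0.5) == []


class TestDetectionSuccessRate:
    @pytest.mark.parametrize(
        "dnl,nlv,expected", [(4, 6, 66.7), (5, 5, 100.0), (0, 4, 0.0)]
    )
    def test_values(self, dnl, nlv, expected):
        assert detection_success_rate(dnl, nlv) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            detection_success_rate(1, 0)
        with pytest.raises(ValueError):
            detection_success_rate(5, 4)
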