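import numpy as np
import pytest

from phenolidar.cloud import PointCloud
from phenolidar.heights import (
    HeightParams,
    detect_plants,
    group_rmse,
    height_error_table,
    mesh_density,
    plant_height,
    ptsthre_for_x,
    select_row_neighborhood,
)
from phenolidar.rows import CropRowLine


class TestRowNeighborhood:
    def test_on_line_kept_far_removed(self):
        line = CropRowLine(90.0, 1.0, 5)
        cloud = PointCloud([[3.0, 1.0, 0.5], [3.0, 1.5, 0.5]])
        out = select_row_neighborhood(cloud, line, margin=0.25)
        assert np.allclose(out.points, [[3.0, 1.0, 0.5]])

    def test_captures_row_points(self, rng):
        stems = np.column_stack([
            rng.uniform(0, 10, 400),
            rng.normal(2.0, 0.02, 400),
            rng.uniform(0, 0.6, 400),
        ])
        out = select_row_neighborhood(PointCloud(stems), CropRowLine(90.0, 2.0, 5), 0.125)
        assert len(out) >= 0.95 * 400


class TestMeshDensity:
    def test_all_points_one_cell(self):
        pts = np.tile([0.05, 0.05, 0.3], (10, 1))
        mesh = mesh_density(pts, BL=0.1)
        assert mesh.Pts.sum() == 10
        assert mesh.Pts.max() == 10

    def test_boundary_point_goes_to_higher_cell(self):
        pts = np.array([[0.0, 0.0, 0], [0.1, 0.0, 0], [0.2, 0.0, 0]])
        mesh = mesh_density(pts, BL=0.1)
        # anchored at min corner: boundaries belong to the upper cell
        assert mesh.Pts[0, 0] == 1 and mesh.Pts[1, 0] == 1 and mesh.Pts[2, 0] == 1

    def test_matches_brute_force_binning(self, rng):
        pts = rng.uniform(0, 3, (2000, 3))
        mesh = mesh_density(pts, BL=0.1)
        assert mesh.Pts.sum() == 2000
        origin = pts[:, :2].min(axis=0)
        for _ in range(30):
            i, j = rng.integers(0, mesh.shape[0]), rng.integers(0, mesh.shape[1])
            lo = origin + 0.1 * np.array([i, j])
            n = np.sum(
                (pts[:, 0] >= lo[0]) & (pts[:, 0] < lo[0] + 0.1)
                & (pts[:, 1] >= lo[1]) & (pts[:, 1] < lo[1] + 0.1)
            )
            assert mesh.Pts[i, j] == n


class TestPtsThre:
    @pytest.mark.parametrize("x,expected", [(3, 80), (5, 80), (6, 30), (8, 30), (9, 10)])
    def test_piecewise_rule(self, x, expected):
        assert ptsthre_for_x(x) == expected

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            ptsthre_for_x(-1.0)

    def test_increasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            HeightParams(ptsthre_rule=((0, 5, 10), (5, np.inf, 80)))


def _mesh_from(pts):
    return mesh_density(np.asarray(pts, dtype=float), BL=0.1)


class TestDetectPlants:
    def test_one_dense_cell(self, rng):
        pts = np.vstack([
            np.tile([1.05, 1.05, 0.3], (120, 1)),
            rng.uniform([0, 0, 0], [2, 2, 0.1], (50, 3)),
        ])
        dets = detect_plants(_mesh_from(pts))
        assert len(dets) == 1

    def test_two_separated_cells_two_detections(self):
        a = np.tile([0.05, 0.05, 0.3], (120, 1))
        b = np.tile([0.45, 0.05, 0.3], (120, 1))
        dets = detect_plants(_mesh_from(np.vstack([a, b])))
        assert len(dets) == 2

    def test_adjacent_dense_cells_merge_into_one(self):
        a = np.tile([0.05, 0.05, 0.3], (120, 1))
        b = np.tile([0.15, 0.05, 0.3], (100, 1))
        dets = detect_plants(_mesh_from(np.vstack([a, b])))
        assert len(dets) == 1
        assert dets[0].seed == (0, 0)  # max-density cell wins

    def test_row_of_plants_no_double_counting(self, rng):
        """12 stems 0.25 m apart, each confined to one 0.1 m cell."""
        stems = []
        for k in range(12):
            cx = 0.05 + 0.25 * k
            stems.append(np.column_stack([
                rng.normal(cx, 0.008, 150),
                rng.normal(0.05, 0.008, 150),
                rng.uniform(0, 0.6, 150),
            ]))
        dets = detect_plants(_mesh_from(np.vstack(stems)))
        assert len(dets) == 12

    def test_translation_equivariance(self, rng):
        pts = np.vstack([
            np.tile([0.35, 0.35, 0.3], (120, 1)),
            rng.uniform([0, 0, 0], [1, 1, 0.1], (40, 3)),
        ])
        dets = detect_plants(_mesh_from(pts))
        shifted = detect_plants(_mesh_from(pts + [0.1, 0.0, 0.0]))
        assert [d.seed for d in shifted] == [d.seed for d in dets]


class TestPlantHeight:
    def test_printed_example_value(self):
        cloud = PointCloud([[0.15, 0.15, 0.651], [0.15, 0.15, 0.2]])
        mesh = mesh_density(cloud.points, BL=0.1)
        from phenolidar.heights import PlantDetection

        det = PlantDetection((0, 0), [(0, 0)], mesh)
        assert plant_height(cloud, det, height_min=0.0) == pytest.approx(0.651)

    def test_flat_ground_gives_zero(self):
        cloud = PointCloud(np.column_stack([np.zeros(10), np.zeros(10), np.full(10, 0.005)]))
        mesh = mesh_density(cloud.points, BL=0.1)
        from phenolidar.heights import PlantDetection

        det = PlantDetection((0, 0), [(0, 0)], mesh)
        assert plant_height(cloud, det, height_min=0.005) == 0.0

    def test_monotone_under_added_higher_point(self, rng):
        pts = rng.uniform([0, 0, 0], [0.3, 0.3, 0.5], (100, 3))
        cloud = PointCloud(pts)
        mesh = mesh_density(pts, BL=0.1)
        from phenolidar.heights import PlantDetection

        det = PlantDetection((1, 1), [(1, 1)], mesh)
        before = plant_height(cloud, det, 0.0)
        higher = PointCloud(np.vstack([pts, [[0.15, 0.15, 0.9]]]))
        det2 = PlantDetection((1, 1), [(1, 1)], mesh)
        assert plant_height(higher, det2, 0.0) >= before

    def test_empty_footprint_rejected(self):
        cloud = PointCloud([[5.0, 5.0, 1.0]])
        mesh = mesh_density(np.array([[0.0, 0.0, 0.0], [5.0, 5.0, 1.0]]), BL=0.1)
        from phenolidar.heights import PlantDetection

        det = PlantDetection((10, 10), [(10, 10)], mesh)
        cloud_far = PointCloud([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            plant_height(cloud_far, det, 0.0)


class TestErrorTables:
    def test_single_plant_error(self):
        df, _ = height_error_table([0.510], [0.651], [3.0])
        assert df.error_m.iloc[0] == pytest.approx(0.141)
        assert df.error_ratio_pct.iloc[0] == pytest.approx(27.65, abs=0.2)

    def test_near_depth_group_rmse(self):
        errors = [0.007, 0.089, 0.055, 0.061, 0.012, 0.033, 0.091, 0.056]
        manual = [0.5] * len(errors)
        computed = [m + e for m, e in zip(manual, errors)]
        df, rmse = height_error_table(manual, computed, [2.0] * len(errors))
        assert round(rmse["0.0 <= x < 5.0"], 3) == 0.058

    def test_perfect_agreement(self):
        df, rmse = height_error_table([0.5, 0.6], [0.5, 0.6], [1.0, 6.0])
        assert (df.error_m == 0).all()
        assert all(v == 0 for v in rmse.values())

    def test_nonpositive_manual_rejected(self):
        with pytest.raises(ValueError):
            height_error_table([0.0], [0.5], [1.0])

    def test_group_rmse_empty_rejected(self):
        with pytest.raises(ValueError):
            group_rmse([])
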