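"""Single-plant detection and plant-height computation.

Along each detected crop row, plants are localized by horizontal point
density: the merged cloud is meshed into square cells of border length ``BL``
(0.1 m) and a cell whose projected point count ``Pts`` exceeds a
depth-dependent threshold ``PtsThre`` is taken to sit on a plant (stems
concentrate returns; density falls off with depth x, hence the piecewise
threshold: 80 for x ≤ 5 m, 30 for 5 < x ≤ 8 m, 10 beyond).  Adjacent
super-threshold cells are merged into one detection (8-connectivity) so a
plant straddling a cell boundary is not counted twice.  Each detection is
expanded to its 3×3 cell neighborhood and the plant height is

    PH = Height_max − Height_min

where ``Height_max`` is the largest elevation among points inside the
neighborhood footprint and ``Height_min`` the global ground reference
``z_min + 0.005`` from ROI abstraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .cloud import PointCloud
from .rows import CropRowLine

__all__ = [
    "HeightParams",
    "GridMesh",
    "PlantDetection",
    "select_row_neighborhood",
    "mesh_density",
    "ptsthre_for_x",
    "detect_plants",
    "plant_height",
    "height_error_table",
    "group_rmse",
]

DEFAULT_PTSTHRE = ((0.0, 5.0, 80), (5.0, 8.0, 30), (8.0, np.inf, 10))
DEFAULT_X_GROUPS = ((0.0, 5.0), (5.0, 8.0), (8.0, np.inf))


@dataclass
class HeightParams:
    """Grid border length BL, depth-dependent density thresholds, ground reference.

    ``ptsthre_rule`` is a tuple of ``(x_lo, x_hi, threshold)`` with thresholds
    non-increasing in depth.  ``row_margin`` bounds the perpendicular distance
    from a row line when carving out its neighborhood; ``height_min`` is the
    global ground reference (z_min + 0.005 m).
    """

    BL: float = 0.1
    ptsthre_rule: tuple = DEFAULT_PTSTHRE
    row_margin: float = 0.25
    height_min: float = 0.0

    def __post_init__(self) -> None:
        if self.BL <= 0:
            raise ValueError("BL must be > 0")
        thresholds = [t for _, _, t in self.ptsthre_rule]
        if any(t <= 0 for t in thresholds):
            raise ValueError("PtsThre thresholds must be > 0")
        if any(later > earlier for earlier, later in zip(thresholds, thresholds[1:])):
            raise ValueError("PtsThre must be non-increasing in x")


def ptsthre_for_x(x: float, rule: tuple = DEFAULT_PTSTHRE) -> int:
    """Depth-dependent cell-density threshold (80 / 30 / 10 by default)."""
    if x < 0:
        raise ValueError("depth x must be >= 0")
    for lo, hi, thr in rule:
        if lo <= x <= hi:
            return int(thr)
    return int(rule[-1][2])


def select_row_neighborhood(
    cloud: PointCloud, row: CropRowLine, margin: float
) -> PointCloud:
    """Points within perpendicular distance ``margin`` of the row line."""
    n = row.normal()
    d = np.abs(cloud.points[:, :2] @ n - row.rho)
    return cloud.with_points(cloud.points[d <= margin])


@dataclass
class GridMesh:
    """Horizontal density mesh: per-cell projected point counts ``Pts``.

    Cells are half-open ``[lo, hi)`` squares of side ``BL`` anchored at the
    bounding-box min corner; a point exactly on a boundary belongs to the
    higher-index cell.
    """

    origin: np.ndarray
    BL: float
    Pts: np.ndarray            # shape (nx, ny)

    @property
    def shape(self) -> tuple[int, int]:
        return self.Pts.shape

    def cell_center(self, i: int, j: int) -> np.ndarray:
        return self.origin + self.BL * (np.array([i, j]) + 0.5)

    def cell_of(self, xy: np.ndarray) -> np.ndarray:
        return np.floor((np.asarray(xy) - self.origin) / self.BL).astype(int)


def mesh_density(points: np.ndarray | PointCloud, BL: float = 0.1) -> GridMesh:
    """Mesh the horizontal bounding box and count points per cell.

    Conservation holds exactly: ``Pts.sum()`` equals the number of points.
    """
    if BL <= 0:
        raise ValueError("BL must be > 0")
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, dtype=float)
    xy = pts[:, :2].reshape(-1, 2)
    if len(xy) == 0:
        return GridMesh(np.zeros(2), BL, np.zeros((0, 0), dtype=int))
    origin = xy.min(axis=0)
    cells = np.floor((xy - origin) / BL).astype(int)
    nx, ny = cells.max(axis=0) + 1
    counts = np.zeros((nx, ny), dtype=int)
    np.add.at(counts, (cells[:, 0], cells[:, 1]), 1)
    return GridMesh(origin, BL, counts)


@dataclass
class PlantDetection:
    """One detected plant: seed cell, its 3×3 neighborhood, and (later) PH."""

    seed: tuple[int, int]
    component_cells: list[tuple[int, int]]
    mesh: GridMesh
    PH: float | None = None
    height_max: float | None = None

    @property
    def neighborhood_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners of the 3×3 cell footprint around the seed."""
        i, j = self.seed
        lo = self.mesh.origin + self.mesh.BL * np.array([i - 1, j - 1])
        hi = self.mesh.origin + self.mesh.BL * np.array([i + 2, j + 2])
        return lo, hi


def detect_plants(mesh: GridMesh, params: HeightParams = HeightParams()) -> list[PlantDetection]:
    """Seed plant detections from super-threshold density cells.

    A cell seeds a plant when ``Pts > PtsThre`` at the cell-center depth.
    Super-threshold cells touching each other (8-connectivity) are merged
    into a single detection whose seed is the maximum-density cell, so one
    plant spanning several cells is counted once.
    """
    if mesh.Pts.size == 0:
        return []
    nx, ny = mesh.shape
    xs = mesh.origin[0] + mesh.BL * (np.arange(nx) + 0.5)
    thr = np.array([ptsthre_for_x(max(x, 0.0), params.ptsthre_rule) for x in xs])
    seeds = mesh.Pts > thr[:, None]
    labels, n_comp = ndimage.label(seeds, structure=np.ones((3, 3), dtype=int))
    detections: list[PlantDetection] = []
    for comp in range(1, n_comp + 1):
        cells = np.argwhere(labels == comp)
        dens = mesh.Pts[cells[:, 0], cells[:, 1]]
        seed = tuple(int(v) for v in cells[np.argmax(dens)])
        detections.append(PlantDetection(seed, [tuple(map(int, c)) for c in cells], mesh))
    detections.sort(key=lambda d: d.seed)
    return detections


def plant_height(
    cloud: PointCloud, det: PlantDetection, height_min: float
) -> float:
    """PH = max elevation inside the 3×3 neighborhood minus the ground reference."""
    lo, hi = det.neighborhood_bounds
    pts = cloud.points
    inside = (
        (pts[:, 0] >= lo[0]) & (pts[:, 0] < hi[0])
        & (pts[:, 1] >= lo[1]) & (pts[:, 1] < hi[1])
    )
    if not inside.any():
        raise ValueError("no points inside the 3x3 neighborhood footprint")
    height_max = float(pts[inside, 2].max())
    det.height_max = height_max
    det.PH = height_max - height_min
    return det.PH


def group_rmse(errors) -> float:
    """Root-mean-square of a group's height errors."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error group")
    return float(np.sqrt(np.mean(e**2)))


def height_error_table(
    manual,
    computed,
    x,
    groups: tuple = DEFAULT_X_GROUPS,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-plant height errors and per-depth-group RMSE.

    ``manual`` are reference (hand-measured or ground-truth) heights,
    ``computed`` the pipeline's values, ``x`` each plant's depth.  Error is
    ``|computed − manual|``, the error ratio ``100·error/manual``, and plants
    are grouped by the half-open depth intervals in ``groups`` for the RMSE.
    """
    m = np.asarray(manual, dtype=float)
    c = np.asarray(computed, dtype=float)
    xv = np.asarray(x, dtype=float)
    if not (len(m) == len(c) == len(xv)):
        raise ValueError("manual, computed and x must have equal length")
    if (m <= 0).any():
        raise ValueError("manual heights must be > 0")
    err = np.abs(c - m)
    ratio = 100.0 * err / m

    def label(xi: float) -> str:
        for lo, hi in groups:
            if lo <= xi < hi:
                return f"{lo} <= x < {hi}" if np.isfinite(hi) else f"x >= {lo}"
        return "ungrouped"

    df = pd.DataFrame(
        {
            "manual_m": m,
            "computed_m": c,
            "error_m": err,
            "error_ratio_pct": ratio,
            "x_m": xv,
            "x_group": [label(v) for v in xv],
        }
    )
    rmse = {
        g: group_rmse(sub["error_m"].to_numpy())
        for g, sub in df.groupby("x_group", sort=False)
    }
    return df, rmse
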