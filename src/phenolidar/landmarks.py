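"""Landmark-plate detection in a single scan.

Registration fiducials are 0.40 m × 0.30 m rectangular plates on tripods,
raised at least 0.1 m above the maize canopy beside the parcel.  Because they
stand above everything else, cutting the scan at a canopy-height threshold
leaves only plate returns and sparse noise.  Density-based clustering (DBSCAN
over an octree index) then groups the plate returns: a *core* point has at
least ``MinPts`` points within radius ``E`` (the plate diagonal, 0.52 m), a
*border* point lies within ``E`` of a core point, everything else is *noise*.
Mutually density-reachable cores merge over-segmented fragments into one
cluster per plate.

From each surviving cluster a single upper corner is extracted — X as the
cluster mean, Y as the minimum, Z as the maximum — and a *virtual landmark* is
interpolated from it: a regular grid on the vertical plane through the corner,
spanning the known plate dimensions.  Registering virtual landmarks instead of
raw scans is what keeps cloud fusion cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import PointCloud
from .octree import OctreeIndex

__all__ = [
    "CORE",
    "BORDER",
    "NOISE",
    "DbscanParams",
    "ClusterResult",
    "LandmarkFilterParams",
    "LandmarkDetection",
    "DetectionStats",
    "cut_above_canopy",
    "dbscan",
    "filter_landmark_candidates",
    "extract_corner",
    "make_virtual_landmark",
    "detect_landmarks",
    "detection_success_rate",
]

CORE, BORDER, NOISE = 2, 1, 0
NOISE_LABEL = -1


@dataclass
class DbscanParams:
    """Adjacency radius E (m) and minimum neighbor count MinPts.

    Defaults follow the field setup: E = 0.52 m is the diagonal of the
    landmark plate, MinPts = 5 the smallest integer exceeding dimension + 1.
    """

    E: float = 0.52
    MinPts: int = 5

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be > 0")
        if self.MinPts < 1:
            raise ValueError("MinPts must be >= 1")


@dataclass
class ClusterResult:
    """Per-point cluster labels (``-1`` = noise) and point roles.

    ``point_type[i]`` is one of :data:`CORE`, :data:`BORDER`, :data:`NOISE`.
    Cluster ids are contiguous from 0 in order of discovery.
    """

    labels: np.ndarray
    point_type: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if len(self.labels) else 0

    def cluster_ids(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def cut_above_canopy(cloud: PointCloud, canopy_cut_z: float) -> PointCloud:
    """Keep only points above the canopy threshold (plates + residual noise)."""
    pts = cloud.points
    return cloud.with_points(pts[pts[:, 2] > canopy_cut_z])


def dbscan(
    cloud: PointCloud,
    params: DbscanParams = DbscanParams(),
    index: OctreeIndex | None = None,
) -> ClusterResult:
    """Density-based clustering with octree-accelerated neighbor search.

    A point is a core point when its E-neighborhood (itself included) holds at
    least ``MinPts`` points.  Clusters grow by breadth-first expansion over
    core points; mutually density-reachable cores therefore always end up in
    the same cluster, which is what merges over-segmented plate fragments.
    Border points reachable from several clusters go to the first-discovered
    one (expansion order = ascending point id).
    """
    pts = cloud.points
    n = len(pts)
    labels = np.full(n, NOISE_LABEL, dtype=int)
    ptype = np.full(n, NOISE, dtype=int)
    if n == 0:
        return ClusterResult(labels, ptype)
    if index is None:
        index = OctreeIndex(pts, leaf_size=params.E / 2.0)
    neighbors = [index.radius_query(pts[i], params.E) for i in range(n)]
    core = np.array([len(nb) >= params.MinPts for nb in neighbors])
    ptype[core] = CORE

    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE_LABEL:
            continue
        labels[i] = cluster
        frontier = [i]
        while frontier:
            j = frontier.pop()
            for k in neighbors[j]:
                if labels[k] == NOISE_LABEL:
                    labels[k] = cluster
                    if core[k]:
                        frontier.append(k)
                    else:
                        ptype[k] = BORDER
        cluster += 1
    return ClusterResult(labels, ptype)


@dataclass
class LandmarkFilterParams:
    """Cluster filtering and plate geometry.

    ``ch`` is the minimum vertical extent of a cluster (0.1 m): thin canopy
    residue is rejected while a full plate spans 0.30 m.  ``max_extent_factor``
    bounds the horizontal footprint at that multiple of the plate diagonal,
    guarding against clusters merged across rows (set to ``None`` to disable).
    """

    ch: float = 0.1
    canopy_cut_z: float | None = None
    plate_w: float = 0.40
    plate_h: float = 0.30
    max_extent_factor: float | None = 2.0

    def __post_init__(self) -> None:
        if self.ch <= 0 or self.plate_w <= 0 or self.plate_h <= 0:
            raise ValueError("ch and plate dimensions must be > 0")

    @property
    def plate_diagonal(self) -> float:
        return float(np.hypot(self.plate_w, self.plate_h))


def filter_landmark_candidates(
    clusters: ClusterResult,
    cloud: PointCloud,
    params: LandmarkFilterParams = LandmarkFilterParams(),
) -> list[int]:
    """Cluster ids that look like landmark plates.

    Keeps clusters whose vertical extent (max z − min z) is at least ``ch``;
    optionally rejects clusters whose horizontal extent exceeds
    ``max_extent_factor`` plate diagonals.
    """
    keep: list[int] = []
    for cid in range(clusters.n_clusters):
        ids = clusters.cluster_ids(cid)
        pts = cloud.points[ids]
        if pts[:, 2].max() - pts[:, 2].min() < params.ch:
            continue
        if params.max_extent_factor is not None:
            span = pts[:, :2].max(axis=0) - pts[:, :2].min(axis=0)
            if np.hypot(*span) > params.max_extent_factor * params.plate_diagonal:
                continue
        keep.append(cid)
    return keep


def extract_corner(cluster_points: PointCloud | np.ndarray) -> np.ndarray:
    """Upper corner of a plate cluster: (mean x, min y, max z)."""
    pts = cluster_points.points if isinstance(cluster_points, PointCloud) else np.asarray(cluster_points)
    pts = pts.reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("cannot extract a corner from an empty cluster")
    return np.array([pts[:, 0].mean(), pts[:, 1].min(), pts[:, 2].max()])


def make_virtual_landmark(
    corner: np.ndarray,
    params: LandmarkFilterParams = LandmarkFilterParams(),
    h_step: float = 0.01,
    v_step: float = 0.01,
    frame_id: str = "sensor",
) -> PointCloud:
    """Interpolate a virtual plate cloud from its upper corner.

    The plate plane is assumed perpendicular to the terrain with its normal
    along X (plates stand parallel to the robot's travel direction): the grid
    extends ``plate_w`` along +Y from the min-y corner and ``plate_h`` along
    −Z from the top edge, with the given horizontal/vertical steps.
    """
    if h_step <= 0 or v_step <= 0:
        raise ValueError("interpolation steps must be > 0")
    cx, cy, cz = np.asarray(corner, dtype=float).reshape(3)
    ny = int(np.floor(params.plate_w / h_step + 1e-9)) + 1
    nz = int(np.floor(params.plate_h / v_step + 1e-9)) + 1
    ys = cy + h_step * np.arange(ny)
    zs = cz - v_step * np.arange(nz)
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    pts = np.column_stack([np.full(yy.size, cx), yy.ravel(), zz.ravel()])
    return PointCloud(pts, frame_id=frame_id)


@dataclass
class LandmarkDetection:
    """One detected plate: member point ids, upper corner, virtual cloud."""

    point_ids: np.ndarray
    corner: np.ndarray
    virtual_cloud: PointCloud


def detect_landmarks(
    scan: PointCloud,
    canopy_cut_z: float,
    dbscan_params: DbscanParams = DbscanParams(),
    filter_params: LandmarkFilterParams = LandmarkFilterParams(),
    h_step: float = 0.01,
    v_step: float = 0.01,
) -> list[LandmarkDetection]:
    """Full single-scan landmark detection.

    Composition: canopy cut → octree build → DBSCAN → cluster filtering →
    per-cluster corner extraction + virtual-plate interpolation.  ``scan``
    should already be ROI-abstracted.  Returns a (possibly empty) list sorted
    by corner Y.
    """
    above = cut_above_canopy(scan, canopy_cut_z)
    if len(above) == 0:
        return []
    clusters = dbscan(above, dbscan_params)
    detections: list[LandmarkDetection] = []
    for cid in filter_landmark_candidates(clusters, above, filter_params):
        ids = clusters.cluster_ids(cid)
        corner = extract_corner(above.points[ids])
        vl = make_virtual_landmark(corner, filter_params, h_step, v_step, frame_id=scan.frame_id)
        detections.append(LandmarkDetection(ids, corner, vl))
    detections.sort(key=lambda d: d.corner[1])
    return detections


@dataclass
class DetectionStats:
    """Landmark-detection bookkeeping for one observation plot.

    NLV = landmarks in view, DNL = detected landmarks, DSR = success rate in
    percent, DTD = detection time in ms (informational).
    """

    NLV: int
    DNL: int
    DTD_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.DNL <= self.NLV:
            raise ValueError("DNL must lie in [0, NLV]")

    @property
    def DSR(self) -> float:
        return detection_success_rate(self.DNL, self.NLV)


def detection_success_rate(DNL: int, NLV: int) -> float:
    """Detection success rate 100·DNL/NLV in percent, to one decimal."""
    if NLV <= 0:
        raise ValueError("NLV must be > 0")
    if not 0 <= DNL <= NLV:
        raise ValueError("DNL must lie in [0, NLV]")
    return round(100.0 * DNL / NLV, 1)
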