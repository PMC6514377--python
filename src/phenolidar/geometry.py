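"""Sensor/mount geometry, ROI abstraction, and the blind-zone formula.

The scanner is an annular multi-beam LiDAR raised on a bracket above a mobile
robot.  Because its vertical field of view only reaches down to a maximum
depression angle α, an annular ground region around the robot receives no
returns — the *blind area*.  Its extent is

    D = (H + h) / tan(α)

with ``H`` the bracket height, ``h`` the offset from the LiDAR origin to its
base, and α the maximum depression angle.  Scans are taken at ranges beyond
``D`` so the whole parcel is visible.

ROI abstraction trims a raw 360° scan down to the parcel: the half-annulus
facing away from the parcel is cut, points inside the blind radius or beyond a
maximum range are dropped, manual horizontal X/Y windows are applied, and a
thin bottom slice (default 5 mm above the lowest point) removes ground-level
noise from uneven terrain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud

__all__ = [
    "SensorConfig",
    "SensorMountGeometry",
    "RoiSpec",
    "blind_zone_diameter",
    "packet_rate",
    "abstract_roi",
    "remove_ground_slice",
]


@dataclass
class SensorConfig:
    """Key scanner parameters (defaults: Velodyne HDL64E-S3)."""

    n_lines: int = 64
    vfov_deg: tuple[float, float] = (-24.8, 2.0)
    azimuth_res_deg: float = 0.09
    range_accuracy_m: float = 0.02
    scan_rate_hz: float = 5.0
    points_per_second: int = 1_333_440
    points_per_packet: int = 384

    def __post_init__(self) -> None:
        lo, hi = self.vfov_deg
        if not lo < hi:
            raise ValueError("vfov lower bound must be below upper bound")
        for name in ("n_lines", "azimuth_res_deg", "range_accuracy_m",
                     "scan_rate_hz", "points_per_second", "points_per_packet"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SensorMountGeometry:
    """Bracket height H, LiDAR origin-to-base offset h, max depression angle α."""

    H: float = 0.91
    h: float = 0.25
    alpha_deg: float = 24.8

    def __post_init__(self) -> None:
        if self.H <= 0 or self.h <= 0:
            raise ValueError("H and h must be > 0")
        if not 0 < self.alpha_deg < 90:
            raise ValueError("alpha_deg must lie in (0, 90)")

    @property
    def sensor_height(self) -> float:
        """Height of the LiDAR origin above ground (H + h)."""
        return self.H + self.h


def blind_zone_diameter(geom: SensorMountGeometry) -> float:
    """Extent ``D = (H + h) / tan(α)`` of the ground blind zone, in meters."""
    if not 0 < geom.alpha_deg < 90:
        raise ValueError("alpha_deg must lie in (0, 90)")
    return (geom.H + geom.h) / math.tan(math.radians(geom.alpha_deg))


def packet_rate(points_per_second: float, points_per_packet: float) -> float:
    """Data packets per second: points/s divided by points per packet."""
    if points_per_second <= 0 or points_per_packet <= 0:
        raise ValueError("rates must be > 0")
    return points_per_second / points_per_packet


@dataclass
class RoiSpec:
    """Region-of-interest thresholds for a single observation spot.

    ``heading_deg`` is the direction facing the parcel in the sensor's horizontal
    plane (0° = +X).  Points whose horizontal position has a negative dot
    product with the heading are discarded (the half-annulus away from the
    parcel; dot = 0 is kept).  ``r_min``/``r_max`` bound the horizontal range
    (``r_min`` defaults to the blind-zone extent), and ``x_range``/``y_range``
    are the manually chosen horizontal windows.
    """

    heading_deg: float = 0.0
    r_min: float | None = None
    r_max: float = 120.0
    x_range: tuple[float, float] | None = None
    y_range: tuple[float, float] | None = None
    ground_slice_m: float = 0.005

    def __post_init__(self) -> None:
        if self.ground_slice_m <= 0:
            raise ValueError("ground_slice_m must be > 0")

    def resolved_r_min(self, geom: SensorMountGeometry | None = None) -> float:
        if self.r_min is not None:
            return self.r_min
        return blind_zone_diameter(geom or SensorMountGeometry())


def abstract_roi(
    cloud: PointCloud,
    roi: RoiSpec,
    geom: SensorMountGeometry | None = None,
) -> PointCloud:
    """Cut a sensor-frame scan down to the parcel region of interest.

    Removes (i) the half-annulus opposite the parcel heading, (ii) points with
    horizontal range below ``r_min`` (blind zone) or above ``r_max``, and
    (iii) points outside the manual ``x_range``/``y_range`` windows.  May
    return an empty cloud.
    """
    pts = cloud.points
    if len(pts) == 0:
        return cloud.with_points(pts)
    r_min = roi.resolved_r_min(geom)
    if not r_min < roi.r_max:
        raise ValueError("r_min must be below r_max")
    theta = math.radians(roi.heading_deg)
    heading = np.array([math.cos(theta), math.sin(theta)])
    keep = pts[:, :2] @ heading >= 0.0
    rng = np.hypot(pts[:, 0], pts[:, 1])
    keep &= (rng >= r_min) & (rng <= roi.r_max)
    if roi.x_range is not None:
        keep &= (pts[:, 0] >= roi.x_range[0]) & (pts[:, 0] <= roi.x_range[1])
    if roi.y_range is not None:
        keep &= (pts[:, 1] >= roi.y_range[0]) & (pts[:, 1] <= roi.y_range[1])
    return cloud.with_points(pts[keep])


def remove_ground_slice(
    cloud: PointCloud, delta: float = 0.005
) -> tuple[PointCloud, float]:
    """Drop the bottom ``delta`` slice of the cloud.

    Finds the minimum elevation ``z_min`` and removes every point with
    ``z`` in ``[z_min, z_min + delta]``.  Returns the trimmed cloud and
    ``z_min`` (the later plant-height stage uses ``z_min + delta`` as its
    ground reference).
    """
    if len(cloud) == 0:
        raise ValueError("cannot ground-slice an empty cloud")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    z = cloud.points[:, 2]
    z_min = float(z.min())
    keep = z > z_min + delta
    return cloud.with_points(cloud.points[keep]), z_min
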