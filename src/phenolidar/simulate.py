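"""Synthetic maize parcel and LiDAR scan generator with ground truth.

This module emulates the acquisition geometry of the field campaign so every
pipeline stage can be exercised against known truth: a rectangular parcel of
maize rows perpendicular to the robot path, rectangular 0.40 m × 0.30 m
landmark plates raised above the canopy along the path side, and an annular
64-line scanner with a ground blind zone and ~2 cm range noise.

World frame convention (shared by all modules): X points into the field, Y
along the robot's travel direction, Z up; the ground sits at z ≈ 0 and the
robot path runs at negative X.

The scanner is emulated by *surface sampling*, not ray casting: candidate
points are drawn on plant, plate and ground surfaces, transformed into the
sensor frame, and then filtered by the sensor's constraints —

* vertical field of view and the blind radius of the ground blind zone;
* discrete beam elevations: a candidate survives only if its elevation angle
  falls within a tolerance band around one of the ``n_lines`` beam angles,
  which reproduces the growing vertical gap between scan rings (and hence
  the depth-dependent height underestimation) of a real spinning scanner;
* a ``1/r`` azimuthal density falloff and optional uniform dropout;
* Gaussian range noise applied along the sensor ray.

Plants are a dense vertical stem segment plus a few arched leaf polylines;
stems therefore dominate the projected point density, which is the property
the row-detection and plant-detection stages rely on.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .cloud import PointCloud, write_cloud
from .geometry import SensorConfig, SensorMountGeometry, blind_zone_diameter
from .registration import RigidTransform

__all__ = [
    "FieldSpec",
    "LandmarkSpec",
    "ScanSpec",
    "GroundTruth",
    "build_field",
    "simulate_scan",
    "make_dataset",
]


@dataclass
class FieldSpec:
    """Maize parcel layout and plant morphology.

    Defaults emulate the younger experimental parcel: ~0.6 m plants in rows
    0.6 m apart, rows perpendicular to the robot path.
    """

    n_rows: int = 20
    row_spacing_mean: float = 0.60
    row_spacing_jitter: float = 0.02
    row_length: float = 10.0
    plant_spacing: float = 0.25
    plant_height_mean: float = 0.60
    plant_height_sigma: float = 0.05
    stem_pts_per_m: float = 900.0
    stem_radius: float = 0.012
    leaves_per_plant: int = 4
    leaf_length: float = 0.25
    leaf_pts: int = 30
    ground_pts_per_m2: float = 40.0
    y_offset: float = 1.0       # y of the first row

    def __post_init__(self) -> None:
        if min(self.row_spacing_mean, self.row_length, self.plant_spacing,
               self.plant_height_mean, self.leaf_length) <= 0:
            raise ValueError("all lengths must be > 0")
        if self.row_spacing_jitter < 0 or self.plant_height_sigma < 0:
            raise ValueError("jitter/sigma must be >= 0")
        if self.plant_spacing <= 0.05:
            raise ValueError("plant spacing too small: plants would overlap")


@dataclass
class LandmarkSpec:
    """Landmark plates beside the parcel, raised above the canopy."""

    n_plates: int = 5
    plate_w: float = 0.40
    plate_h: float = 0.30
    clearance: float = 0.10      # bottom edge this far above the canopy
    plate_x: float = -0.8        # plates between path and parcel edge
    surface_step: float = 0.02
    y_positions: tuple[float, ...] | None = None  # default: spread along the parcel

    def __post_init__(self) -> None:
        if self.clearance < 0.10:
            raise ValueError("plate clearance must be at least 0.1 m above the plants")


@dataclass
class ScanSpec:
    """Per-viewpoint sensing model.

    ``spot_spacing`` is the distance between adjacent observation spots along
    the path (~1 m).  ``noise_sigma`` is the 1-σ range accuracy (0.02 m).
    ``beam_tol_frac`` is the half-width of the beam acceptance band as a
    fraction of the local beam spacing (controls how strongly surface samples
    are thinned into scan rings).
    """

    sensor: SensorConfig = field(default_factory=SensorConfig)
    mount: SensorMountGeometry = field(default_factory=SensorMountGeometry)
    noise_sigma: float = 0.02
    dropout: float = 0.0
    spot_spacing: float = 1.0
    path_x: float = -3.5
    yaw_sigma_deg: float = 0.5
    beam_tol_frac: float = 0.15
    range_falloff_ref: float = 2.0   # r0 in the min(1, r0/r) azimuth keep probability
    occlusion: bool = True           # shadow points whose ray grazes a nearer stem
    canopy_transmittance: float = 0.85  # per-plant-canopy Beer-Lambert transmittance
    beam_divergence_rad: float = 0.002  # laser footprint growth; drives thin-target dropout

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def blind_radius(self) -> float:
        return blind_zone_diameter(self.mount)


@dataclass
class GroundTruth:
    """Everything the generator knows about the world it built."""

    plants: list[dict]                  # row_num, crop_num, position, height
    row_y: np.ndarray                   # y of each row line
    row_lines: list[dict]               # theta_deg, rho per row
    landmark_corners: np.ndarray        # upper (mean-x, min-y, max-z) corner per plate
    viewpoints: list[RigidTransform]    # sensor pose in the world frame per spot
    z_ground: float = 0.0
    stem_radius: float = 0.012
    target_widths: np.ndarray | None = None  # per world point, for thin-target dropout

    @property
    def row_spacings(self) -> np.ndarray:
        return np.diff(np.sort(self.row_y))

    @property
    def stems(self) -> np.ndarray:
        """``(n, 3)`` stem top points (x, y, height) for occlusion modeling."""
        return np.array(
            [[p["position"][0], p["position"][1], p["height"]] for p in self.plants]
        ).reshape(-1, 3)


def _sample_plant(rng: np.random.Generator, base: np.ndarray, height: float,
                  spec: FieldSpec) -> tuple[np.ndarray, np.ndarray]:
    """Stem segment plus arched leaves, sampled to points.

    Returns the points and a per-point effective target width: the stem
    tapers from its full diameter at the base to a thin whorl at the top,
    and leaves are narrow throughout — at long range these thin structures
    underfill the laser footprint and return sparsely.
    """
    n_stem = max(4, int(spec.stem_pts_per_m * height))
    z = rng.uniform(0.0, height, n_stem)
    stem_r = spec.stem_radius
    ang = rng.uniform(0, 2 * np.pi, n_stem)
    stem = np.column_stack([
        base[0] + stem_r * np.cos(ang),
        base[1] + stem_r * np.sin(ang),
        z,
    ])
    stem_w = 2 * stem_r * (1.0 - 0.7 * z / height)
    parts = [stem]
    widths = [stem_w]
    for _ in range(spec.leaves_per_plant):
        azim = rng.uniform(0, 2 * np.pi)
        attach = rng.uniform(0.4, 0.85) * height
        t = rng.uniform(0, 1, spec.leaf_pts)
        # circular-ish arc rising then drooping in a vertical plane
        radial = spec.leaf_length * t
        lift = 0.35 * spec.leaf_length * np.sin(np.pi * np.minimum(t * 1.2, 1.0))
        leaf = np.column_stack([
            base[0] + radial * np.cos(azim),
            base[1] + radial * np.sin(azim),
            attach + lift - 0.25 * spec.leaf_length * t**2,
        ])
        parts.append(leaf)
        # leaf blades narrow from ~25 mm near the stem to tips
        widths.append(0.025 * (1.0 - 0.8 * t))
    return np.vstack(parts), np.concatenate(widths)


def build_field(
    field_spec: FieldSpec = FieldSpec(),
    lm_spec: LandmarkSpec = LandmarkSpec(),
    seed: int = 0,
    scan_spec: ScanSpec | None = None,
    n_spots: int = 10,
) -> tuple[PointCloud, GroundTruth]:
    """Generate the world cloud and its ground truth.

    Rows run along X (into the field, perpendicular to the path); row i sits
    at ``y_offset + i·spacing`` with per-row jitter.  Landmark plates are
    planar point grids at ``plate_x`` with their bottom edge ``clearance``
    above the canopy.  Viewpoint poses place the sensor origin at
    ``(path_x, y_k, H + h)`` with spots ``spot_spacing`` apart; the global
    frame is the sensor frame at the *last* spot.
    """
    rng = np.random.default_rng(seed)
    scan_spec = scan_spec or ScanSpec()

    offsets = field_spec.row_spacing_mean + rng.normal(
        0.0, field_spec.row_spacing_jitter, field_spec.n_rows - 1
    ) if field_spec.n_rows > 1 else np.empty(0)
    row_y = field_spec.y_offset + np.concatenate([[0.0], np.cumsum(offsets)])

    parts: list[np.ndarray] = []
    widths: list[np.ndarray] = []
    plants: list[dict] = []
    n_per_row = int(np.floor(field_spec.row_length / field_spec.plant_spacing)) + 1
    for ri, y in enumerate(row_y):
        for ci in range(n_per_row):
            x = ci * field_spec.plant_spacing
            h = max(0.2, rng.normal(field_spec.plant_height_mean, field_spec.plant_height_sigma))
            base = np.array([x, y, 0.0])
            pts_p, w_p = _sample_plant(rng, base, h, field_spec)
            parts.append(pts_p)
            widths.append(w_p)
            plants.append({
                "row_num": ri + 1,
                "crop_num": ci + 1,
                "position": [float(x), float(y)],
                "height": float(h),
            })

    # ground: uniform scatter over the parcel plus the strip toward the path
    x_lo = min(scan_spec.path_x, -1.5)
    x_hi = field_spec.row_length + 0.5
    y_lo, y_hi = row_y.min() - 1.0, row_y.max() + 1.0
    area = (x_hi - x_lo) * (y_hi - y_lo)
    n_ground = int(field_spec.ground_pts_per_m2 * area)
    ground = np.column_stack([
        rng.uniform(x_lo, x_hi, n_ground),
        rng.uniform(y_lo, y_hi, n_ground),
        np.zeros(n_ground),
    ])
    parts.append(ground)
    widths.append(np.full(n_ground, np.inf))  # extended surface

    # landmark plates: vertical planar grids with normal along X
    canopy_top = field_spec.plant_height_mean + 2 * field_spec.plant_height_sigma
    z_bot = canopy_top + lm_spec.clearance
    if lm_spec.y_positions is not None:
        plate_y = np.asarray(lm_spec.y_positions, dtype=float)
    else:
        plate_y = np.linspace(row_y.min(), row_y.max(), lm_spec.n_plates)
        plate_y = plate_y + rng.uniform(-0.15, 0.15, len(plate_y))
    # uniform random surface samples (a regular grid would alias against the
    # discrete beam elevations of the scan model)
    corners = []
    n_plate = int((lm_spec.plate_w / lm_spec.surface_step + 1)
                  * (lm_spec.plate_h / lm_spec.surface_step + 1))
    for py in plate_y:
        plate = np.column_stack([
            np.full(n_plate, lm_spec.plate_x),
            rng.uniform(py, py + lm_spec.plate_w, n_plate),
            rng.uniform(z_bot, z_bot + lm_spec.plate_h, n_plate),
        ])
        parts.append(plate)
        widths.append(np.full(n_plate, np.inf))  # extended surface
        corners.append([lm_spec.plate_x, float(py), float(z_bot + lm_spec.plate_h)])

    world = PointCloud(np.vstack(parts), frame_id="world")

    # sensor->world poses: straight path with small per-spot yaw wobble
    sensor_z = scan_spec.mount.sensor_height
    y_start = row_y.min()
    viewpoints = []
    for k in range(n_spots):
        pos = np.array([scan_spec.path_x, y_start + k * scan_spec.spot_spacing, sensor_z])
        yaw = np.radians(rng.normal(0.0, scan_spec.yaw_sigma_deg))
        c, s = np.cos(yaw), np.sin(yaw)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        viewpoints.append(RigidTransform(R, pos))

    truth = GroundTruth(
        plants=plants,
        row_y=row_y,
        row_lines=[{"theta_deg": 90.0, "rho": float(y)} for y in row_y],
        landmark_corners=np.asarray(corners).reshape(-1, 3),
        viewpoints=viewpoints,
        z_ground=0.0,
        stem_radius=field_spec.stem_radius,
        target_widths=np.concatenate(widths),
    )
    return world, truth


def _occlusion_keep(
    pts: np.ndarray,
    stems_sensor: np.ndarray,
    stem_radius: float,
    canopy_radius: float,
    transmittance: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shadow mask combining hard stem blocking and soft canopy attenuation.

    A ray is blocked outright when it passes within ``stem_radius`` (in
    azimuth) of a nearer stem below that stem's top.  Each additional pass
    through a nearer plant's *canopy* cylinder (radius ``canopy_radius``)
    multiplies the survival probability by ``transmittance`` — a Beer–Lambert
    style foliage model: rays to deep plants cross many canopies, so both
    point density and top coverage fall off with depth.  Plants do not shadow
    their own returns (a small range guard band is excluded).
    """
    az = np.arctan2(pts[:, 1], pts[:, 0])
    r = np.hypot(pts[:, 0], pts[:, 1])
    order = np.argsort(az)
    az_sorted = az[order]
    keep = np.ones(len(pts), dtype=bool)
    crossings = np.zeros(len(pts), dtype=np.int32)
    s_r = np.hypot(stems_sensor[:, 0], stems_sensor[:, 1])
    s_az = np.arctan2(stems_sensor[:, 1], stems_sensor[:, 0])
    s_top = stems_sensor[:, 2]
    for az_c, r_c, top_c in zip(s_az, s_r, s_top):
        if r_c < 1e-6:
            continue
        half_w = np.arcsin(min(1.0, canopy_radius / r_c))
        lo = np.searchsorted(az_sorted, az_c - half_w)
        hi = np.searchsorted(az_sorted, az_c + half_w)
        if hi <= lo:
            continue
        cand = order[lo:hi]
        behind = r[cand] > r_c + 2 * canopy_radius
        # ray elevation at the stem's range must stay below the plant top
        under = pts[cand, 2] * (r_c / np.maximum(r[cand], 1e-9)) < top_c
        hit = behind & under
        crossings[cand[hit]] += 1
        if stem_radius > 0:
            core = np.abs(az[cand] - az_c) <= np.arcsin(min(1.0, stem_radius / r_c))
            keep[cand[hit & core]] = False
    if transmittance < 1.0:
        keep &= rng.random(len(pts)) < transmittance**crossings
    return keep


def simulate_scan(
    world: PointCloud,
    pose: RigidTransform,
    scan: ScanSpec = ScanSpec(),
    seed: int = 0,
    stems: np.ndarray | None = None,
    stem_radius: float = 0.012,
    canopy_radius: float = 0.15,
    target_widths: np.ndarray | None = None,
) -> PointCloud:
    """One annular scan of ``world`` from the sensor pose (sensor frame).

    ``pose`` maps sensor-frame coordinates to the world frame; the returned
    cloud is in the sensor frame.  ``stems`` (world-frame ``(n, 3)`` stem top
    points) enables the stem-shadowing approximation when the scan spec asks
    for occlusion.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    pts = pose.inverse().apply(world.points)
    widths = (np.asarray(target_widths, dtype=float)
              if target_widths is not None else np.full(len(pts), np.inf))
    rng_h = np.hypot(pts[:, 0], pts[:, 1])
    r = np.linalg.norm(pts, axis=1)
    ok = r > 1e-9
    pts, rng_h, r, widths = pts[ok], rng_h[ok], r[ok], widths[ok]

    elev = np.degrees(np.arctan2(pts[:, 2], rng_h))
    lo, hi = scan.sensor.vfov_deg
    keep = (elev >= lo) & (elev <= hi) & (rng_h >= scan.blind_radius)

    # discrete beam elevations: keep candidates near a scan ring
    if scan.sensor.n_lines > 1:
        spacing = (hi - lo) / (scan.sensor.n_lines - 1)
        off = (elev - lo) / spacing
        frac = np.abs(off - np.round(off))
        keep &= frac <= scan.beam_tol_frac
    # azimuthal density falloff with range
    if scan.range_falloff_ref > 0:
        keep &= rng.random(len(pts)) < np.minimum(1.0, scan.range_falloff_ref / np.maximum(r, 1e-9))
    # thin-target dropout: structures narrower than the laser footprint
    # (divergence x range) return with reduced probability
    if scan.beam_divergence_rad > 0:
        footprint = scan.beam_divergence_rad * r
        fill = np.minimum(1.0, widths / np.maximum(footprint, 1e-9))
        keep &= rng.random(len(pts)) < fill
    if scan.dropout > 0:
        keep &= rng.random(len(pts)) >= scan.dropout

    pts = pts[keep]
    r = r[keep]
    if scan.occlusion and stems is not None and len(stems) and len(pts):
        stems_sensor = pose.inverse().apply(stems)
        occ = _occlusion_keep(pts, stems_sensor, stem_radius, canopy_radius,
                              scan.canopy_transmittance, rng)
        pts = pts[occ]
        r = r[occ]
    if scan.noise_sigma > 0 and len(pts):
        ray = pts / r[:, None]
        pts = pts + ray * rng.normal(0.0, scan.noise_sigma, len(pts))[:, None]
    return PointCloud(pts, frame_id="sensor")


def make_dataset(
    out_dir: str,
    field_spec: FieldSpec = FieldSpec(),
    lm_spec: LandmarkSpec = LandmarkSpec(),
    scan_spec: ScanSpec = ScanSpec(),
    n_spots: int = 10,
    seed: int = 0,
) -> dict:
    """Write a reproducible synthetic dataset to ``out_dir``.

    Produces ``spot_XX.pcd`` per viewpoint (sensor frame), ``world.pcd``,
    ``truth.json`` (poses, plants, rows, plate corners) and the generation
    config; rerunning with the same seed reproduces the files bit-identically.
    """
    os.makedirs(out_dir, exist_ok=True)
    world, truth = build_field(field_spec, lm_spec, seed=seed,
                               scan_spec=scan_spec, n_spots=n_spots)
    write_cloud(world, os.path.join(out_dir, "world.pcd"))
    spot_files = []
    for k, pose in enumerate(truth.viewpoints):
        scan = simulate_scan(world, pose, scan_spec, seed=seed + 1000 + k,
                             stems=truth.stems, stem_radius=truth.stem_radius,
                             target_widths=truth.target_widths)
        path = os.path.join(out_dir, f"spot_{k + 1:02d}.pcd")
        write_cloud(scan, path)
        spot_files.append(path)
    payload = {
        "seed": seed,
        "n_spots": n_spots,
        "field": asdict(field_spec),
        "landmarks": {k: v for k, v in asdict(lm_spec).items()},
        "scan": {
            "noise_sigma": scan_spec.noise_sigma,
            "dropout": scan_spec.dropout,
            "spot_spacing": scan_spec.spot_spacing,
            "path_x": scan_spec.path_x,
            "blind_radius": scan_spec.blind_radius,
        },
        "plants": truth.plants,
        "row_y": truth.row_y.tolist(),
        "row_lines": truth.row_lines,
        "landmark_corners": truth.landmark_corners.tolist(),
        "poses": [
            {"R": p.R.tolist(), "T": p.T.tolist()} for p in truth.viewpoints
        ],
        "z_ground": truth.z_ground,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(payload, fh, indent=1)
    return {"world": os.path.join(out_dir, "world.pcd"),
            "spots": spot_files,
            "truth": os.path.join(out_dir, "truth.json")}
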