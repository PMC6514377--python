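"""End-to-end orchestration: scans → ROI → landmarks → fusion → rows → heights.

The framework runs the four processing steps in order — landmark detection,
registration/fusion, row-spacing calculation, plant-height computation — on a
set of per-spot scans, and (when ground truth is available, e.g. for the
bundled simulator) emits an evaluation report mirroring the usual field
bookkeeping: a per-spot landmark table (NLV/DNL/DSR), a row-spacing table with
R² and RMSE against truth, and a per-plant height table with depth-grouped
RMSE.  All randomness is seeded, so a rerun with the same configuration is
bit-identical.
"""

from __future__ import annotations

import glob
import json
import os
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
import yaml

from .cloud import PointCloud, read_cloud
from .geometry import RoiSpec, SensorConfig, SensorMountGeometry, abstract_roi, remove_ground_slice
from .heights import (
    HeightParams,
    PlantDetection,
    detect_plants,
    height_error_table,
    mesh_density,
    plant_height,
    select_row_neighborhood,
)
from .landmarks import DbscanParams, LandmarkFilterParams, detect_landmarks, detection_success_rate
from .registration import (
    RegistrationError,
    RigidTransform,
    merge_clouds,
    register_via_landmarks,
    select_plots,
)
from .rows import (
    CropRowLine,
    RowSpacingResult,
    band_histograms,
    eval_regression,
    find_peaks,
    hough_rows,
    project_to_plane,
    row_spacings,
)

__all__ = ["PipelineConfig", "PipelineResult", "EvaluationReport", "run_pipeline", "write_report"]


@dataclass
class RegistrationConfig:
    step: int = 3
    seed: int = 0
    method: str = "auto"
    tol: float = 1e-4
    max_iter: int = 50
    h_step: float = 0.01
    v_step: float = 0.01


@dataclass
class RowsConfig:
    band_width: float = 1.0
    bin_width: float = 0.02
    theta_min: float = 75.0
    theta_max: float = 105.0
    theta_res: float = 0.5
    rho_res: float = 0.02
    min_support: int = 3
    peak_min_count: int = 5
    peak_window: int = 2
    peak_rel_threshold: float = 0.3


@dataclass
class AnalysisConfig:
    """Horizontal crop of the merged (global-frame) cloud for rows/heights."""

    x_range: tuple[float, float] | None = None
    y_range: tuple[float, float] | None = None


@dataclass
class PipelineConfig:
    sensor: SensorConfig = field(default_factory=SensorConfig)
    mount: SensorMountGeometry = field(default_factory=SensorMountGeometry)
    roi: RoiSpec = field(default_factory=RoiSpec)
    dbscan: DbscanParams = field(default_factory=DbscanParams)
    lm_filter: LandmarkFilterParams = field(default_factory=LandmarkFilterParams)
    # canopy height threshold above the scan's own ground level (z_min); plates
    # sit >= 0.1 m above the plants, so cutting at the canopy top isolates them
    canopy_cut_above_ground: float = 0.70
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    rows: RowsConfig = field(default_factory=RowsConfig)
    heights: HeightParams = field(default_factory=HeightParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build a config from nested dicts, rejecting unknown keys."""
        kwargs = {}
        known = {f.name: f for f in dc_fields(cls)}
        for key, val in data.items():
            if key not in known:
                raise ValueError(f"unknown config section {key!r}")
            f = known[key]
            if isinstance(val, dict):
                sub_cls = f.default_factory().__class__ if f.default_factory is not None else None
                sub_known = {sf.name for sf in dc_fields(sub_cls)}
                unknown = set(val) - sub_known
                if unknown:
                    raise ValueError(f"unknown keys in config section {key!r}: {sorted(unknown)}")
                val = {k: tuple(v) if isinstance(v, list) else v for k, v in val.items()}
                kwargs[key] = sub_cls(**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class EvaluationReport:
    dsr_table: pd.DataFrame
    row_table: pd.DataFrame
    row_r2: float | None
    row_rmse: float | None
    height_table: pd.DataFrame
    height_group_rmse: dict[str, float]


@dataclass
class PipelineResult:
    merged: PointCloud
    z_min: float
    transforms: list[RigidTransform]
    selected: list[int]
    row_lines: list[CropRowLine]
    spacings: RowSpacingResult
    plant_detections: list[tuple[int, PlantDetection]]   # (row index, detection)
    report: EvaluationReport | None
    log: list[str]


class _Truth:
    """Thin accessor over the simulator's truth.json payload."""

    def __init__(self, data: dict):
        self.data = data
        self.row_y = np.asarray(data["row_y"], dtype=float)
        self.plants = data["plants"]
        self.poses = [
            RigidTransform(np.asarray(p["R"]), np.asarray(p["T"])) for p in data["poses"]
        ]
        self.n_plates = len(data["landmark_corners"])

    @classmethod
    def load(cls, path: str) -> "_Truth":
        with open(path) as fh:
            return cls(json.load(fh))


def _load_dataset(data_dir: str) -> tuple[list[PointCloud], _Truth | None]:
    paths = sorted(glob.glob(os.path.join(data_dir, "spot_*.pcd")))
    if not paths:
        raise FileNotFoundError(f"no spot_*.pcd scans in {data_dir}")
    scans = [read_cloud(p) for p in paths]
    truth_path = os.path.join(data_dir, "truth.json")
    truth = _Truth.load(truth_path) if os.path.exists(truth_path) else None
    return scans, truth


def run_pipeline(
    config: PipelineConfig,
    scans: list[PointCloud] | str,
    truth: _Truth | str | None = None,
) -> PipelineResult:
    """Execute the full framework on per-spot scans (or a dataset directory).

    Scans are 1-based "plots"; every ``registration.step``-th one is selected,
    consecutive selected scans are registered via their virtual landmarks, and
    all are composed into the frame of the last selected scan (the global
    frame).  Rows and plant heights are then extracted from the merged cloud.
    When ground truth is supplied the evaluation report is populated.
    """
    log: list[str] = []
    if isinstance(scans, str):
        scans, loaded_truth = _load_dataset(scans)
        truth = truth if truth is not None else loaded_truth
    if isinstance(truth, str):
        truth = _Truth.load(truth)
    if len(scans) < 2:
        raise ValueError("need at least 2 scans")

    cfg = config
    selected = select_plots(len(scans), cfg.registration.step)
    log.append(f"selected plots (step={cfg.registration.step}): {selected}")

    # --- stage 1+2: ROI, landmark detection, pairwise registration, fusion
    roi_scans = [abstract_roi(scans[i - 1], cfg.roi, cfg.mount) for i in selected]
    log.append(f"ROI point counts: {[len(s) for s in roi_scans]}")
    canopy_z = [
        float(s.points[:, 2].min()) + cfg.canopy_cut_above_ground for s in roi_scans
    ]
    detections = [
        detect_landmarks(s, cz, cfg.dbscan, cfg.lm_filter,
                         cfg.registration.h_step, cfg.registration.v_step)
        for s, cz in zip(roi_scans, canopy_z)
    ]
    log.append(f"landmarks detected per selected plot: {[len(d) for d in detections]}")

    m = len(roi_scans)
    rel: list[RigidTransform] = []
    for i in range(m - 1):
        try:
            res = register_via_landmarks(
                roi_scans[i], roi_scans[i + 1], canopy_z[i],
                cfg.dbscan, cfg.lm_filter,
                cfg.registration.h_step, cfg.registration.v_step,
                method=cfg.registration.method, seed=cfg.registration.seed + i,
                max_iter=cfg.registration.max_iter, tol=cfg.registration.tol,
            )
        except RegistrationError as exc:
            raise RegistrationError(
                f"registration stage failed between plots {selected[i]} and {selected[i+1]}: {exc}"
            ) from exc
        rel.append(res.transform)
        log.append(
            f"registered plot {selected[i]}->{selected[i+1]}: rms={res.rms_residual:.4f} m "
            f"({res.method}, {res.n_iterations} it)"
        )
    to_global: list[RigidTransform] = [RigidTransform.identity() for _ in range(m)]
    for i in range(m - 2, -1, -1):
        to_global[i] = to_global[i + 1].compose(rel[i])
    merged = merge_clouds(roi_scans, to_global)
    log.append(f"merged cloud: {len(merged)} points")

    # --- analysis crop (manual horizontal thresholds), then ground slice:
    # the ground reference z_min is taken within the parcel region itself
    x_range, y_range = cfg.analysis.x_range, cfg.analysis.y_range
    if (x_range is None or y_range is None) and truth is not None:
        auto_x, auto_y = _auto_analysis_crop(truth, selected)
        x_range = x_range if x_range is not None else auto_x
        y_range = y_range if y_range is not None else auto_y
        log.append(f"analysis crop from dataset config: x={x_range}, y={y_range}")
    pts = merged.points
    keep = np.ones(len(pts), dtype=bool)
    if x_range is not None:
        keep &= (pts[:, 0] >= x_range[0]) & (pts[:, 0] <= x_range[1])
    if y_range is not None:
        keep &= (pts[:, 1] >= y_range[0]) & (pts[:, 1] <= y_range[1])
    analysis_cloud, z_min = remove_ground_slice(
        merged.with_points(pts[keep], "global"), cfg.roi.ground_slice_m
    )
    height_min = z_min + cfg.roi.ground_slice_m
    log.append(f"analysis cloud: {len(analysis_cloud)} points, z_min={z_min:.4f} m")

    # --- stage 3: row spacing
    xy = project_to_plane(analysis_cloud)
    hists = band_histograms(xy, cfg.rows.band_width, cfg.rows.bin_width)
    peaks = [
        p
        for h in hists
        for p in find_peaks(h, cfg.rows.peak_min_count, cfg.rows.peak_window,
                            cfg.rows.peak_rel_threshold)
    ]
    lines = hough_rows(
        peaks, (cfg.rows.theta_min, cfg.rows.theta_max),
        cfg.rows.theta_res, cfg.rows.rho_res, cfg.rows.min_support,
    )
    x_mid = float(xy[:, 0].mean()) if len(xy) else 0.0
    spacing_result = row_spacings(lines, x_mid=x_mid)
    log.append(f"rows: {len(lines)} lines, {len(spacing_result)} spacings")

    # --- stage 4: plant heights
    plant_dets: list[tuple[int, PlantDetection]] = []
    hp = HeightParams(
        BL=cfg.heights.BL, ptsthre_rule=cfg.heights.ptsthre_rule,
        row_margin=cfg.heights.row_margin, height_min=height_min,
    )
    for ri, line in enumerate(spacing_result.lines):
        neigh = select_row_neighborhood(analysis_cloud, line, hp.row_margin)
        if len(neigh) == 0:
            continue
        mesh = mesh_density(neigh, hp.BL)
        for det in detect_plants(mesh, hp):
            plant_height(neigh, det, height_min)
            plant_dets.append((ri, det))
    log.append(f"plants detected: {len(plant_dets)}")

    report = None
    if truth is not None:
        report = _evaluate(cfg, detections, selected, spacing_result, plant_dets, truth)
    return PipelineResult(
        merged, z_min, to_global, selected, lines, spacing_result, plant_dets, report, log
    )


def _auto_analysis_crop(truth: "_Truth", selected: list[int]):
    """Parcel crop in the global frame, derived from the dataset's layout
    config (parcel geometry is operator knowledge, not measurement truth)."""
    field_cfg = truth.data.get("field", {})
    scan_cfg = truth.data.get("scan", {})
    if not field_cfg or not scan_cfg:
        return None, None
    path_x = scan_cfg["path_x"]
    spot_spacing = scan_cfg.get("spot_spacing", 1.0)
    y0 = field_cfg.get("y_offset", 1.0)
    n_rows = field_cfg["n_rows"]
    spacing = field_cfg["row_spacing_mean"]
    length = field_cfg["row_length"]
    y_last = y0 + (selected[-1] - 1) * spot_spacing
    x_range = (-path_x - 0.5, -path_x + length + 0.7)
    y_range = (y0 - y_last - 0.4, y0 + (n_rows - 1) * spacing - y_last + 0.4 + 0.02 * n_rows)
    return x_range, y_range


def _evaluate(cfg, detections, selected, spacing_result, plant_dets, truth: _Truth) -> EvaluationReport:
    # landmark table: per selected plot
    rows = []
    for plot, dets in zip(selected, detections):
        nlv = truth.n_plates
        dnl = min(len(dets), nlv)
        rows.append({"plot": plot, "NLV": nlv, "DNL": dnl,
                     "DSR_pct": detection_success_rate(dnl, nlv)})
    dsr_table = pd.DataFrame(rows)

    # world -> global frame (last selected scan's sensor frame)
    pose_last = truth.poses[selected[-1] - 1]
    world_to_global = pose_last.inverse()

    # row spacings: match detected lines to truth rows by global Y position
    truth_y = np.sort(world_to_global.apply(
        np.column_stack([np.full_like(truth.row_y, 5.0), truth.row_y, np.zeros_like(truth.row_y)])
    )[:, 1])
    est_y = np.array([l.y_at(0.0) for l in spacing_result.lines]) if spacing_result.lines else np.empty(0)
    row_rows, est_rs, true_rs = [], [], []
    if len(est_y) >= 2:
        order = np.argsort(est_y)
        est_sorted = est_y[order]
        matched_truth = [truth_y[np.argmin(np.abs(truth_y - y))] for y in est_sorted]
        for i in range(len(est_sorted) - 1):
            est = est_sorted[i + 1] - est_sorted[i]
            tru = matched_truth[i + 1] - matched_truth[i]
            if tru <= 0:
                continue
            est_rs.append(est)
            true_rs.append(tru)
            row_rows.append({"index": i + 1, "truth_m": tru, "estimate_m": est,
                             "error_m": abs(est - tru)})
    row_table = pd.DataFrame(row_rows)
    row_r2 = row_rmse = None
    if len(est_rs) >= 2:
        row_r2, row_rmse = eval_regression(est_rs, true_rs)

    # plant heights: match detections to nearest true plant (<= 0.2 m)
    tp = np.array([p["position"] for p in truth.plants], dtype=float)
    th = np.array([p["height"] for p in truth.plants], dtype=float)
    tp_global = world_to_global.apply(
        np.column_stack([tp, np.zeros(len(tp))])
    )[:, :2]
    manual, computed, xs = [], [], []
    used: set[int] = set()
    for _, det in plant_dets:
        c = det.mesh.cell_center(*det.seed)
        d2 = np.sum((tp_global - c) ** 2, axis=1)
        j = int(np.argmin(d2))
        if d2[j] > 0.2**2 or j in used:
            continue
        used.add(j)
        manual.append(th[j])
        computed.append(det.PH)
        xs.append(c[0])
    if manual:
        height_table, group_rmse = height_error_table(manual, computed, xs)
    else:
        height_table, group_rmse = pd.DataFrame(), {}
    return EvaluationReport(dsr_table, row_table, row_r2, row_rmse, height_table, group_rmse)


def write_report(report: EvaluationReport, out_dir: str) -> dict[str, str]:
    """Write the report tables as CSV plus a short text summary."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    dsr_path = os.path.join(out_dir, "landmark_detection.csv")
    report.dsr_table.to_csv(dsr_path, index=False)
    paths["dsr"] = dsr_path
    rows_path = os.path.join(out_dir, "row_spacing.csv")
    report.row_table.to_csv(rows_path, index=False)
    paths["rows"] = rows_path
    h_path = os.path.join(out_dir, "plant_height.csv")
    report.height_table.to_csv(h_path, index=False)
    paths["heights"] = h_path
    lines = ["phenolidar evaluation summary", "=" * 30]
    if len(report.dsr_table):
        lines.append(f"mean DSR: {report.dsr_table['DSR_pct'].mean():.1f}%")
    if report.row_rmse is not None:
        lines.append(f"row spacing: R2={report.row_r2:.4f}  RMSE={report.row_rmse:.4f} m "
                     f"({len(report.row_table)} spacings)")
    for g, r in report.height_group_rmse.items():
        lines.append(f"plant height RMSE [{g}]: {r:.3f} m")
    summary = os.path.join(out_dir, "summary.txt")
    with open(summary, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    paths["summary"] = summary
    return paths
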