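"""Crop-row detection and row-spacing computation.

Maize rows run nearly perpendicular to the robot's travel direction (the Y
axis of the global frame).  Projected onto the horizontal plane, a stem
produces many more returns per unit area than leaves, so rows show up as peaks
in Y-histograms.  The procedure:

(a) tile the ROI into equal-width *depth bands* parallel to the travel
    direction (intervals in X, the depth axis);
(b) histogram each band's points along Y;
(c) take local histogram maxima as candidate in-row points;
(d) vote the candidates into a Hough accumulator constrained to line angles
    of 75°–105° from the Y axis (rows ≈ perpendicular to travel) with a
    minimum support of 3 peaks per line;
(e) report row spacing (RS) as the perpendicular distance between adjacent
    lines, evaluated at the ROI's X midline since detected lines need not be
    exactly parallel.

Angle convention: ``theta`` is the angle of the line *direction* measured from
the Y axis, so ``theta = 90°`` is a row exactly perpendicular to travel.  A
line is ``{p : -cos(theta)·x + sin(theta)·y = rho}``; at 90° ``rho`` is simply
the row's Y position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cloud import PointCloud

__all__ = [
    "DepthBand",
    "BandHistogram",
    "PeakPoint",
    "CropRowLine",
    "RowSpacingResult",
    "project_to_plane",
    "band_histograms",
    "find_peaks",
    "hough_rows",
    "row_spacings",
    "eval_regression",
]


@dataclass(frozen=True)
class DepthBand:
    x_lo: float
    x_hi: float

    @property
    def center(self) -> float:
        return 0.5 * (self.x_lo + self.x_hi)


@dataclass
class BandHistogram:
    band: DepthBand
    bin_width: float
    y0: float                 # left edge of bin 0
    counts: np.ndarray

    def bin_center(self, i: int) -> float:
        return self.y0 + (i + 0.5) * self.bin_width


@dataclass(frozen=True)
class PeakPoint:
    x: float
    y: float
    count: int


@dataclass
class CropRowLine:
    theta_deg: float
    rho: float
    support: int

    def normal(self) -> np.ndarray:
        t = np.radians(self.theta_deg)
        return np.array([-np.cos(t), np.sin(t)])

    def y_at(self, x: float) -> float:
        t = np.radians(self.theta_deg)
        s = np.sin(t)
        if abs(s) < 1e-9:
            raise ValueError("line parallel to Y axis has no y(x)")
        return (self.rho + np.cos(t) * x) / s


@dataclass
class RowSpacingResult:
    spacings: np.ndarray      # RS values, ordered along Y
    lines: list[CropRowLine]

    def __len__(self) -> int:
        return len(self.spacings)


def project_to_plane(cloud: PointCloud) -> np.ndarray:
    """Drop Z: ``(n, 2)`` horizontal coordinates, count and duplicates preserved."""
    return cloud.points[:, :2].copy()


def band_histograms(
    points2d: np.ndarray, band_width: float = 1.0, bin_width: float = 0.02
) -> list[BandHistogram]:
    """Per-depth-band Y histograms with a shared bin grid.

    Bands tile ``[min x, max x]`` with equal width; the Y bin edges are global
    so peak positions are comparable across bands.  Total counts over all
    bands equal the number of input points.
    """
    if band_width <= 0 or bin_width <= 0:
        raise ValueError("band_width and bin_width must be > 0")
    pts = np.asarray(points2d, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return []
    x_lo, x_hi = pts[:, 0].min(), pts[:, 0].max()
    y_lo, y_hi = pts[:, 1].min(), pts[:, 1].max()
    n_bands = max(1, int(np.ceil((x_hi - x_lo) / band_width - 1e-9)))
    n_bins = max(1, int(np.ceil((y_hi - y_lo) / bin_width - 1e-9)))
    y_edges = y_lo + bin_width * np.arange(n_bins + 1)
    out: list[BandHistogram] = []
    band_idx = np.minimum(((pts[:, 0] - x_lo) / band_width).astype(int), n_bands - 1)
    for b in range(n_bands):
        sel = pts[band_idx == b, 1]
        counts, _ = np.histogram(sel, bins=y_edges)
        out.append(
            BandHistogram(
                DepthBand(x_lo + b * band_width, x_lo + (b + 1) * band_width),
                bin_width,
                float(y_lo),
                counts,
            )
        )
    return out


def find_peaks(
    hist: BandHistogram, min_count: int = 5, window: int = 2,
    rel_threshold: float = 0.0,
) -> list[PeakPoint]:
    """Local maxima of one band histogram.

    A bin is a peak when its count is at least ``min_count`` and maximal over
    the ±``window`` neighborhood; on plateaus of equal counts only the
    lowest-Y bin is reported.  ``rel_threshold`` additionally requires a peak
    to reach that fraction of the band's maximum count — stems tower over the
    leaf/ground background by an order of magnitude, and a relative threshold
    tracks the point-density falloff with depth where an absolute one cannot.
    """
    c = hist.counts
    floor = max(float(min_count), rel_threshold * (c.max() if len(c) else 0))
    peaks: list[PeakPoint] = []
    for i in range(len(c)):
        if c[i] < floor:
            continue
        lo = max(0, i - window)
        hi = min(len(c), i + window + 1)
        if any(c[j] > c[i] for j in range(lo, hi)):
            continue
        if any(c[j] == c[i] for j in range(lo, i)):
            continue  # tie resolved to the lower-y bin
        peaks.append(PeakPoint(hist.band.center, hist.bin_center(i), int(c[i])))
    return peaks


def _rho_of(xy: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
    """Signed normal offsets, shape (n_points, n_thetas)."""
    t = np.radians(theta_deg)
    return -np.outer(xy[:, 0], np.cos(t)) + np.outer(xy[:, 1], np.sin(t))


def hough_rows(
    peaks: list[PeakPoint],
    theta_range: tuple[float, float] = (75.0, 105.0),
    theta_res: float = 0.5,
    rho_res: float = 0.02,
    min_support: int = 3,
) -> list[CropRowLine]:
    """Angle-constrained Hough transform over in-row candidate peaks.

    Peaks vote into a (theta, rho) accumulator restricted to ``theta_range``.
    Lines are extracted greedily: the strongest cell wins, its supporting
    peaks (rho within half a bin at the winning angle) are assigned to the
    line and removed, and voting repeats until no cell reaches
    ``min_support``.  Each line is refined by a principal-axis fit to its
    supporting peaks (kept only if the refined angle stays inside the range).
    Returns lines sorted by rho; fewer than ``min_support`` peaks yield none.
    """
    if len(peaks) < min_support:
        return []
    xy = np.array([[p.x, p.y] for p in peaks], dtype=float)
    thetas = np.arange(theta_range[0], theta_range[1] + theta_res / 2, theta_res)
    remaining = np.ones(len(peaks), dtype=bool)
    lines: list[CropRowLine] = []
    while remaining.sum() >= min_support:
        rho = _rho_of(xy[remaining], thetas)
        rho_min = rho.min()
        bins = np.round((rho - rho_min) / rho_res).astype(int)
        n_rho = bins.max() + 1
        acc = np.zeros((len(thetas), n_rho), dtype=int)
        idx_rem = np.flatnonzero(remaining)
        for ti in range(len(thetas)):
            np.add.at(acc[ti], bins[:, ti], 1)
        ti, ri = np.unravel_index(np.argmax(acc), acc.shape)
        if acc[ti, ri] < min_support:
            break
        members = idx_rem[bins[:, ti] == ri]
        theta_star = float(thetas[ti])
        # refine by principal-axis fit through the supporting peaks
        m = xy[members]
        if len(m) >= 2:
            centered = m - m.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            u = vt[0]
            # angle of the direction vector from the Y axis, mapped to [0, 180)
            theta_fit = float(np.degrees(np.arctan2(u[0], u[1]))) % 180.0
            if theta_range[0] <= theta_fit <= theta_range[1]:
                theta_star = theta_fit
        t = np.radians(theta_star)
        rho_star = float(np.mean(-m[:, 0] * np.cos(t) + m[:, 1] * np.sin(t)))
        lines.append(CropRowLine(theta_star, rho_star, int(len(members))))
        # non-maximum suppression: retire every peak within two rho bins of
        # the refined line so one dense row cannot spawn near-duplicate lines
        rho_all = -xy[idx_rem, 0] * np.cos(t) + xy[idx_rem, 1] * np.sin(t)
        remaining[idx_rem[np.abs(rho_all - rho_star) <= 2 * rho_res]] = False
        remaining[members] = False
    lines.sort(key=lambda l: l.rho)
    return lines


def row_spacings(lines: list[CropRowLine], x_mid: float = 0.0) -> RowSpacingResult:
    """Adjacent-line spacings, ordered along Y.

    Lines are sorted by their normal offset; each spacing is the distance
    between consecutive lines measured along their mean normal at the ROI's
    X midline (robust to slightly non-parallel lines).  Fewer than two lines
    yield an empty result.
    """
    if len(lines) < 2:
        return RowSpacingResult(np.empty(0), list(lines))
    srt = sorted(lines, key=lambda l: l.y_at(x_mid))
    rs = []
    for a, b in zip(srt[:-1], srt[1:]):
        pa = np.array([x_mid, a.y_at(x_mid)])
        pb = np.array([x_mid, b.y_at(x_mid)])
        n = a.normal() + b.normal()
        n /= np.linalg.norm(n)
        rs.append(abs(float((pb - pa) @ n)))
    return RowSpacingResult(np.asarray(rs), srt)


def eval_regression(estimates, truths) -> tuple[float, float]:
    """(R², RMSE) of estimates against reference values.

    RMSE is the root-mean-square difference; R² is the coefficient of
    determination of the least-squares line of estimates on truths.
    """
    e = np.asarray(estimates, dtype=float)
    t = np.asarray(truths, dtype=float)
    if e.shape != t.shape:
        raise ValueError("estimates and truths must have equal length")
    if e.size < 2:
        raise ValueError("need at least 2 pairs")
    rmse = float(np.sqrt(np.mean((e - t) ** 2)))
    if np.allclose(e, e[0]) or np.allclose(t, t[0]):
        r2 = 1.0 if np.allclose(e, t) else 0.0
    else:
        r2 = float(stats.linregress(t, e).rvalue ** 2)
    return r2, rmse
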