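"""Rigid registration of observation scans via virtual landmarks.

Scans taken from neighboring observation spots differ by an (almost planar)
rigid motion: a large translation along the robot's path and a small rotation.
Registering the raw million-point scans directly would be expensive, so the
pipeline registers the lightweight *virtual landmark* clouds instead and then
applies the recovered transform ``R′, T′`` to the full scans.

Two stages, as is standard for feature-based registration:

1. coarse alignment — per-point FPFH descriptors (33-bin fast point feature
   histograms) drive a sample-consensus initial alignment (SAC-IA): random
   triplets of feature correspondences propose rigid transforms which are
   scored by nearest-neighbor agreement;
2. fine alignment — point-to-point ICP (nearest-neighbor correspondences and
   a closed-form Kabsch update each iteration), whose residual is provably
   non-increasing.

A deterministic corner-correspondence alternative (mutual nearest neighbors
after centroid shift, solved in closed form) is available whenever at least
three landmarks are visible on both sides; it doubles as a fallback when
sample consensus fails to find agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .landmarks import DbscanParams, LandmarkFilterParams, detect_landmarks

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "RegistrationError",
    "kabsch",
    "estimate_normals",
    "fpfh_features",
    "coarse_align",
    "icp_refine",
    "register_via_landmarks",
    "merge_clouds",
    "select_plots",
]

_ORTHO_TOL = 1e-9


class RegistrationError(RuntimeError):
    pass


@dataclass
class RigidTransform:
    """Rotation ``R`` (3×3, orthonormal, det = +1) plus translation ``T`` (m)."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    T: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.T = np.asarray(self.T, dtype=float).reshape(3)
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=1e-8):
            raise ValueError("R is not orthonormal")
        if not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-8):
            raise ValueError("R is not a proper rotation (det != 1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points).reshape(-1, 3) @ self.R.T + self.T

    def apply_cloud(self, cloud: PointCloud, frame_id: str | None = None) -> PointCloud:
        return PointCloud(self.apply(cloud.points), frame_id or cloud.frame_id)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply *other* first, then *self*."""
        return RigidTransform(self.R @ other.R, self.R @ other.T + self.T)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.T)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.R) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms_residual: float
    n_iterations: int
    converged: bool
    method: str = "icp"


def kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform minimizing ``Σ‖R·src + T − dst‖²``.

    Closed-form SVD solution (with the usual reflection fix).  Requires at
    least three non-collinear matched pairs.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst, dtype=float).reshape(-1, 3)
    if len(src) != len(dst):
        raise ValueError("src and dst must have equal length")
    if len(src) < 3:
        raise ValueError("need at least 3 matched pairs")
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    A = src - mu_s
    B = dst - mu_d
    # collinear configurations leave a rotation axis undetermined
    if np.linalg.matrix_rank(A, tol=1e-10 * max(1.0, np.abs(A).max())) < 2:
        raise ValueError("matched points are collinear")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    T = mu_d - R @ mu_s
    return RigidTransform(R, T)


# --------------------------------------------------------------------------
# FPFH features


def estimate_normals(points: np.ndarray, radius: float) -> np.ndarray:
    """Per-point unit normals from PCA of the fixed-radius neighborhood.

    The sign is made deterministic by forcing the largest-magnitude component
    positive (only relative angles enter the feature histograms).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    tree = cKDTree(pts)
    normals = np.zeros_like(pts)
    neighborhoods = tree.query_ball_point(pts, radius)
    for i, nb in enumerate(neighborhoods):
        if len(nb) < 3:
            normals[i] = (0.0, 0.0, 1.0)
            continue
        q = pts[nb] - pts[nb].mean(axis=0)
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        n = vt[-1]
        k = np.argmax(np.abs(n))
        normals[i] = n if n[k] >= 0 else -n
    return normals


def _spfh(pts: np.ndarray, normals: np.ndarray, radius: float, n_bins: int = 11):
    tree = cKDTree(pts)
    pairs_src: list[int] = []
    pairs_dst: list[int] = []
    for i, nb in enumerate(tree.query_ball_point(pts, radius)):
        for j in nb:
            if j != i:
                pairs_src.append(i)
                pairs_dst.append(j)
    n = len(pts)
    hist = np.zeros((n, 3 * n_bins))
    if not pairs_src:
        return hist, np.array(pairs_src), np.array(pairs_dst), np.empty(0)
    si = np.asarray(pairs_src)
    di = np.asarray(pairs_dst)
    d = pts[di] - pts[si]
    dist = np.linalg.norm(d, axis=1)
    ok = dist > 1e-12
    si, di, d, dist = si[ok], di[ok], d[ok], dist[ok]
    dn = d / dist[:, None]
    u = normals[si]
    v = np.cross(dn, u)
    vn = np.linalg.norm(v, axis=1)
    vn[vn < 1e-12] = 1.0
    v /= vn[:, None]
    w = np.cross(u, v)
    n2 = normals[di]
    alpha = np.einsum("ij,ij->i", v, n2)                      # in [-1, 1]
    phi = np.einsum("ij,ij->i", u, dn)                        # in [-1, 1]
    theta = np.arctan2(np.einsum("ij,ij->i", w, n2),
                       np.einsum("ij,ij->i", u, n2))          # in [-pi, pi]
    for k, (feat, lo, hi) in enumerate(
        ((alpha, -1.0, 1.0), (phi, -1.0, 1.0), (theta, -np.pi, np.pi))
    ):
        b = np.clip(((feat - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
        np.add.at(hist, (si, k * n_bins + b), 1.0)
    # histograms deliberately keep raw counts (no per-point normalization):
    # on planar plate grids every pair angle is identical, and only the
    # neighborhood mass distinguishes interior, edge and corner points
    return hist, si, di, dist


def fpfh_features(points: np.ndarray, radius: float, n_bins: int = 11) -> np.ndarray:
    """33-bin fast point feature histograms (simplified, fixed-radius).

    SPFH angles (α, φ, θ) of each neighbor pair are binned into three
    ``n_bins`` histograms; the final descriptor adds the distance-weighted
    mean of the neighbors' SPFHs.  Histograms are non-negative, one per point,
    and keep raw counts so that boundary points remain distinguishable even on
    geometry where all pair angles coincide (e.g. planar plates).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    normals = estimate_normals(pts, radius)
    spfh, si, di, dist = _spfh(pts, normals, radius, n_bins)
    fpfh = spfh.copy()
    if len(si):
        w = 1.0 / np.maximum(dist, 1e-9)
        acc = np.zeros_like(spfh)
        np.add.at(acc, si, spfh[di] * w[:, None])
        wsum = np.zeros(len(pts))
        np.add.at(wsum, si, w)
        wsum[wsum == 0] = 1.0
        fpfh += acc / wsum[:, None]
    return fpfh


# --------------------------------------------------------------------------
# coarse alignment (SAC-IA)


def coarse_align(
    src_vl: PointCloud,
    dst_vl: PointCloud,
    feature_radius: float = 0.03,
    n_samples: int = 8000,
    seed: int = 0,
    min_sample_distance: float = 0.2,
    inlier_threshold: float = 0.05,
    k_candidates: int = 10,
    score_subsample: int = 200,
    min_inlier_fraction: float = 0.75,
    max_rotation_deg: float = 30.0,
) -> RigidTransform:
    """Sample-consensus initial alignment over FPFH correspondences.

    Repeatedly samples three well-separated source points, draws for each a
    random candidate among its ``k_candidates`` nearest destination points in
    feature space, rejects triplets whose pairwise distances disagree between
    the two clouds (cheap rigidity check), solves the closed-form transform
    for the survivors and scores them by nearest-neighbor consensus on a
    fixed subsample: primarily the fraction of points within
    ``inlier_threshold`` of the destination, ties broken by truncated RMS.
    Deterministic given ``seed``.  Raises :class:`RegistrationError` when the
    best hypothesis aligns fewer than ``min_inlier_fraction`` of the points.
    """
    src = src_vl.points
    dst = dst_vl.points
    if len(src) == 0 or len(dst) == 0:
        raise RegistrationError("coarse_align requires non-empty clouds")
    rng = np.random.default_rng(seed)
    f_src = fpfh_features(src, feature_radius)
    f_dst = fpfh_features(dst, feature_radius)

    # Sample only feature-salient points: on repetitive geometry (five
    # identical plates) interior points share one histogram and carry no
    # correspondence information; rare features (plate corners/edges) do.
    def salient(f: np.ndarray) -> np.ndarray:
        k = min(9, len(f))
        d, _ = cKDTree(f).query(f, k=k)
        rarity = d[:, -1] if d.ndim > 1 else d
        n_keep = max(min(24, len(f)), int(0.005 * len(f)))
        return np.argsort(rarity)[-n_keep:]

    sal_src = salient(f_src)
    sal_dst = salient(f_dst)
    ftree = cKDTree(f_dst[sal_dst])
    _, knn_local = ftree.query(f_src[sal_src], k=min(k_candidates, len(sal_dst)))
    knn = sal_dst[np.atleast_2d(knn_local)]
    dtree = cKDTree(dst)
    sub = src if len(src) <= score_subsample else src[
        rng.choice(len(src), score_subsample, replace=False)
    ]
    best: RigidTransform | None = None
    best_frac = -1.0
    best_rms = np.inf
    trunc = inlier_threshold
    for _ in range(n_samples):
        picks = rng.choice(len(sal_src), size=3, replace=False)
        p = src[sal_src[picks]]
        d01 = np.linalg.norm(p[0] - p[1])
        d02 = np.linalg.norm(p[0] - p[2])
        d12 = np.linalg.norm(p[1] - p[2])
        if min(d01, d02, d12) < min_sample_distance:
            continue
        cand = knn[picks, rng.integers(0, knn.shape[1], size=3)]
        q = dst[cand]
        # rigidity prefilter: pairwise distances must agree between clouds
        if (
            abs(np.linalg.norm(q[0] - q[1]) - d01) > 2 * trunc
            or abs(np.linalg.norm(q[0] - q[2]) - d02) > 2 * trunc
            or abs(np.linalg.norm(q[1] - q[2]) - d12) > 2 * trunc
        ):
            continue
        try:
            t = kabsch(p, q)
        except ValueError:
            continue
        # acquisition regime: consecutive spots differ by a large translation
        # but only a small rotation; zero-thickness plate constellations are
        # near-symmetric under 180° flips, which this constraint excludes
        if t.rotation_angle_deg() > max_rotation_deg:
            continue
        d, _ = dtree.query(t.apply(sub), k=1)
        frac = float(np.mean(d <= trunc))
        rms = float(np.sqrt(np.mean(np.minimum(d, trunc) ** 2)))
        if frac > best_frac or (frac == best_frac and rms < best_rms):
            best_frac = frac
            best_rms = rms
            best = t
    if best is None or best_frac < min_inlier_fraction:
        raise RegistrationError(
            f"SAC-IA found no consensus (best inlier fraction {max(best_frac, 0):.2f})"
        )
    return best


# --------------------------------------------------------------------------
# fine alignment (ICP)


def icp_refine(
    src: PointCloud,
    dst: PointCloud,
    init: RigidTransform | None = None,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> RegistrationResult:
    """Point-to-point ICP with closed-form rigid updates.

    Alternates nearest-neighbor correspondence search against ``dst`` with a
    Kabsch update; the RMS residual is non-increasing across iterations and
    iteration stops when it improves by less than ``tol`` (meters) or after
    ``max_iter`` rounds.
    """
    if len(src) == 0 or len(dst) == 0:
        raise RegistrationError("icp_refine requires non-empty clouds")
    t = init or RigidTransform.identity()
    tree = cKDTree(dst.points)
    prev = np.inf
    rms = np.inf
    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        moved = t.apply(src.points)
        d, idx = tree.query(moved, k=1)
        rms = float(np.sqrt(np.mean(d**2)))
        if prev - rms < tol:
            converged = True
            break
        prev = rms
        try:
            t = kabsch(src.points, dst.points[idx])
        except ValueError:
            break  # degenerate correspondences; keep last transform
    return RegistrationResult(t, rms, n_it, converged)


def _match_corners(
    corners_src: np.ndarray, corners_dst: np.ndarray, min_pairs: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of mutual-nearest-neighbor corner pairs after centroid shift."""
    a = corners_src - corners_src.mean(axis=0)
    b = corners_dst - corners_dst.mean(axis=0)
    ta, tb = cKDTree(a), cKDTree(b)
    _, ab = tb.query(a, k=1)
    _, ba = ta.query(b, k=1)
    pairs = [(i, j) for i, j in enumerate(ab) if ba[j] == i]
    if len(pairs) < min_pairs:
        raise RegistrationError(f"fewer than {min_pairs} mutual corner matches")
    i, j = np.array(pairs).T
    return i, j


def register_via_landmarks(
    src_scan: PointCloud,
    dst_scan: PointCloud,
    canopy_cut_z: float,
    dbscan_params: DbscanParams = DbscanParams(),
    filter_params: LandmarkFilterParams = LandmarkFilterParams(),
    h_step: float = 0.01,
    v_step: float = 0.01,
    method: str = "auto",
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-4,
    rms_gate: float = 0.05,
) -> RegistrationResult:
    """Estimate the rigid transform carrying ``src_scan`` into ``dst_scan``'s frame.

    Landmarks are detected independently in both scans, their virtual plate
    clouds pooled, coarsely aligned and ICP-refined; the resulting transform
    applies to the full scans.  ``method`` is one of ``"auto"`` (SAC-IA with a
    corner-correspondence fallback), ``"sacia"``, or ``"corners"``.
    """
    det_src = detect_landmarks(src_scan, canopy_cut_z, dbscan_params, filter_params, h_step, v_step)
    det_dst = detect_landmarks(dst_scan, canopy_cut_z, dbscan_params, filter_params, h_step, v_step)
    if not det_src or not det_dst:
        raise RegistrationError(
            f"landmark detection failed (src: {len(det_src)}, dst: {len(det_dst)} plates)"
        )
    vl_src = PointCloud(np.vstack([d.virtual_cloud.points for d in det_src]), src_scan.frame_id)
    vl_dst = PointCloud(np.vstack([d.virtual_cloud.points for d in det_dst]), dst_scan.frame_id)

    def corner_init() -> RigidTransform:
        # Pair plates by mutual-NN corners, then solve over the pooled matched
        # virtual grids point-for-point (grids share one layout per plate, so
        # the correspondence is exact).  Corners alone are nearly collinear
        # along the path and leave the rotation about that line undetermined.
        cs = np.array([d.corner for d in det_src])
        cd = np.array([d.corner for d in det_dst])
        i, j = _match_corners(cs, cd, min_pairs=2)
        a = np.vstack([det_src[k].virtual_cloud.points for k in i])
        b = np.vstack([det_dst[k].virtual_cloud.points for k in j])
        return kabsch(a, b)

    used = method
    if method == "corners":
        init = corner_init()
    elif method == "sacia":
        init = coarse_align(vl_src, vl_dst, feature_radius=3 * max(h_step, v_step), seed=seed)
    elif method == "auto":
        try:
            init = coarse_align(vl_src, vl_dst, feature_radius=3 * max(h_step, v_step), seed=seed)
            used = "sacia"
        except RegistrationError:
            init = corner_init()
            used = "corners"
    else:
        raise ValueError(f"unknown method {method!r}")
    result = icp_refine(vl_src, vl_dst, init, max_iter=max_iter, tol=tol)
    result.method = f"{used}+icp"
    if method == "auto" and used == "sacia" and result.rms_residual > rms_gate:
        # sample consensus can lock onto a shifted plate assignment when the
        # plate layout is near-uniform; the final residual exposes it
        try:
            alt = icp_refine(vl_src, vl_dst, corner_init(), max_iter=max_iter, tol=tol)
        except (RegistrationError, ValueError):
            return result
        if alt.rms_residual < result.rms_residual:
            alt.method = "corners+icp"
            return alt
    return result


def merge_clouds(
    clouds: list[PointCloud],
    transforms: list[RigidTransform],
    frame_id: str = "global",
) -> PointCloud:
    """Concatenate clouds after mapping each into the common frame."""
    if len(clouds) != len(transforms):
        raise ValueError("need exactly one transform per cloud")
    if not clouds:
        return PointCloud(np.empty((0, 3)), frame_id)
    parts = [t.apply(c.points) for c, t in zip(clouds, transforms)]
    return PointCloud(np.vstack(parts), frame_id)


def select_plots(n_plots: int, step: int) -> list[int]:
    """Every ``step``-th observation plot: ``step, 2·step, …`` (1-based).

    With 30 plots, steps 1/2/3 select 30/15/10 plots.  A step beyond
    ``n_plots`` degenerates to the single last plot.
    """
    if n_plots < 1 or step < 1:
        raise ValueError("n_plots and step must be >= 1")
    if step > n_plots:
        return [n_plots]
    return list(range(step, n_plots + 1, step))
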