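"""Point-cloud container and file I/O.

The package's universal currency is :class:`PointCloud`: an ``(n, 3)`` array of
XYZ coordinates in meters plus a frame label (``"sensor"`` for raw per-spot
scans, ``"global"`` after fusion).  Three interchange dialects are supported:

* PCD — ASCII read/write, binary little-endian read-only.  ASCII PCD is the
  canonical dialect used between pipeline stages.
* PLY — ASCII read/write (delegated to :mod:`trimesh`).
* XYZ/CSV — one ``x y z`` (whitespace- or comma-separated) triple per line.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointCloud", "read_cloud", "write_cloud", "CloudParseError"]


class CloudParseError(ValueError):
    """Raised when a point-cloud file cannot be parsed; names the offending line."""


@dataclass
class PointCloud:
    """An ordered set of 3D points in meters.

    Parameters
    ----------
    points
        Array-like of shape ``(n, 3)``.  Coordinates must be finite.
    frame_id
        Non-empty label of the coordinate frame the points live in.
    """

    points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    frame_id: str = "sensor"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if not np.isfinite(pts).all():
            raise ValueError("point coordinates must be finite")
        if not self.frame_id:
            raise ValueError("frame_id must be non-empty")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def xyz(self) -> np.ndarray:
        return self.points

    def with_points(self, points: np.ndarray, frame_id: str | None = None) -> "PointCloud":
        return PointCloud(points, frame_id or self.frame_id)


# --------------------------------------------------------------------------
# format detection

_FORMATS = ("pcd", "ply", "xyz")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower().lstrip(".")
        if f in ("csv", "txt"):
            f = "xyz"
        if f not in _FORMATS:
            raise ValueError(f"unsupported point-cloud format: {fmt!r}")
        return f
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("csv", "txt"):
        ext = "xyz"
    if ext not in _FORMATS:
        raise ValueError(f"cannot infer format from extension of {path!r}")
    return ext


# --------------------------------------------------------------------------
# PCD

_PCD_HEADER_KEYS = ("FIELDS", "SIZE", "TYPE", "COUNT", "WIDTH", "HEIGHT", "POINTS", "DATA")


def _read_pcd(path: str) -> np.ndarray:
    with open(path, "rb") as fh:
        header: dict[str, list[str]] = {}
        lineno = 0
        while True:
            raw = fh.readline()
            lineno += 1
            if not raw:
                raise CloudParseError(f"{path}:{lineno}: truncated PCD header")
            line = raw.decode("ascii", errors="replace").strip()
            if not line or line.startswith("#"):
                continue
            key, *vals = line.split()
            header[key.upper()] = vals
            if key.upper() == "DATA":
                break
        for k in ("FIELDS", "POINTS", "DATA"):
            if k not in header:
                raise CloudParseError(f"{path}: PCD header missing {k}")
        fields = [f.lower() for f in header["FIELDS"]]
        try:
            idx = [fields.index(c) for c in ("x", "y", "z")]
        except ValueError:
            raise CloudParseError(f"{path}: PCD FIELDS lack x/y/z: {fields}") from None
        n = int(header["POINTS"][0])
        mode = header["DATA"][0].lower()
        if mode == "ascii":
            rows = np.empty((n, 3))
            for i in range(n):
                raw = fh.readline()
                lineno += 1
                if not raw:
                    raise CloudParseError(f"{path}:{lineno}: expected {n} data rows, got {i}")
                parts = raw.split()
                try:
                    rows[i] = [float(parts[j]) for j in idx]
                except (ValueError, IndexError):
                    raise CloudParseError(
                        f"{path}:{lineno}: non-numeric or short data row"
                    ) from None
            return rows
        if mode == "binary":
            sizes = [int(s) for s in header.get("SIZE", ["4"] * len(fields))]
            types = header.get("TYPE", ["F"] * len(fields))
            counts = [int(c) for c in header.get("COUNT", ["1"] * len(fields))]
            fmt_map = {("F", 4): "f", ("F", 8): "d", ("I", 4): "i", ("U", 4): "I",
                       ("I", 2): "h", ("U", 2): "H", ("I", 1): "b", ("U", 1): "B",
                       ("I", 8): "q", ("U", 8): "Q"}
            if any(c != 1 for c in counts):
                raise CloudParseError(f"{path}: PCD COUNT>1 fields unsupported")
            try:
                codes = [fmt_map[(t.upper(), s)] for t, s in zip(types, sizes)]
            except KeyError:
                raise CloudParseError(f"{path}: unsupported PCD binary field type") from None
            dt = np.dtype({
                "names": [f"f{i}" for i in range(len(fields))],
                "formats": ["<" + c for c in codes],
            })
            blob = fh.read(dt.itemsize * n)
            if len(blob) < dt.itemsize * n:
                raise CloudParseError(f"{path}: binary PCD payload truncated")
            arr = np.frombuffer(blob, dtype=dt)
            return np.column_stack([arr[f"f{i}"].astype(float) for i in idx])
        raise CloudParseError(f"{path}: unsupported PCD DATA mode {mode!r}")


def _write_pcd(points: np.ndarray, path: str) -> None:
    n = len(points)
    with open(path, "w") as fh:
        fh.write(
            "# .PCD v0.7 - Point Cloud Data file format\n"
            "VERSION 0.7\nFIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
            f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
        )
        np.savetxt(fh, points, fmt="%.7g")


# --------------------------------------------------------------------------
# PLY (via trimesh) and XYZ/CSV


def _read_ply(path: str) -> np.ndarray:
    import trimesh

    try:
        obj = trimesh.load(path, file_type="ply", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad headers
        raise CloudParseError(f"{path}: malformed PLY ({exc})") from exc
    verts = np.asarray(obj.vertices, dtype=float)
    return verts.reshape(-1, 3)


def _write_ply(points: np.ndarray, path: str) -> None:
    import trimesh

    trimesh.points.PointCloud(points.reshape(-1, 3)).export(
        path, file_type="ply", encoding="ascii"
    )


def _read_xyz(path: str) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise CloudParseError(f"{path}:{lineno}: expected 3 coordinates")
            try:
                rows.append([float(p) for p in parts[:3]])
            except ValueError:
                raise CloudParseError(f"{path}:{lineno}: non-numeric coordinate") from None
    return np.asarray(rows, dtype=float).reshape(-1, 3)


def _write_xyz(points: np.ndarray, path: str) -> None:
    np.savetxt(path, points.reshape(-1, 3), fmt="%.7g")


# --------------------------------------------------------------------------
# public API

_READERS = {"pcd": _read_pcd, "ply": _read_ply, "xyz": _read_xyz}
_WRITERS = {"pcd": _write_pcd, "ply": _write_ply, "xyz": _write_xyz}


def read_cloud(path: str, format: str | None = None, frame_id: str = "sensor") -> PointCloud:
    """Read a point cloud from *path*.

    ``format`` is one of ``"pcd"``, ``"ply"``, ``"xyz"`` (aliases ``csv``/``txt``);
    when omitted it is inferred from the file extension.
    """
    fmt = _infer_format(path, format)
    return PointCloud(_READERS[fmt](path), frame_id=frame_id)


def write_cloud(cloud: PointCloud, path: str, format: str | None = None) -> None:
    """Write *cloud* to *path* in the named (or extension-inferred) dialect."""
    fmt = _infer_format(path, format)
    _WRITERS[fmt](cloud.points, path)
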