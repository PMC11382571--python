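"""Point-cloud data model, file I/O, and cleanup operations.

Coordinates are meters throughout; no unit metadata is read from files.
Supported on-disk dialects:

* PLY — ``element vertex`` with float ``x y z`` and optional uchar
  ``red green blue``; binary-little-endian (default on write) and ASCII.
* PCD — v0.7 ASCII, fields ``x y z`` or ``x y z rgb`` (packed float RGB).
* XYZ — whitespace-separated ``x y z`` or ``x y z r g b`` rows.

Coordinates are held in float64 in memory.  PLY/PCD are written float32 by
default (the common tooling convention), which bounds round-trip precision
at roughly 1e-7 relative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "BoundingVolume",
    "CloudFormatError",
    "load_cloud",
    "write_cloud",
    "crop_to_bounds",
    "remove_duplicates",
    "remove_statistical_outliers",
    "load_bounds",
]

PathLike = Union[str, Path]


class CloudFormatError(ValueError):
    """Raised when a cloud file cannot be parsed or written."""


@dataclass
class PointCloud:
    """An unordered set of 3D points with optional per-point RGB color.

    Parameters
    ----------
    points
        ``(N, 3)`` float64 array of coordinates in meters.
    colors
        Optional ``(N, 3)`` uint8 array of RGB values.
    """

    points: np.ndarray
    colors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if self.points.shape[0] < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors)
            if self.colors.shape != self.points.shape:
                raise ValueError(
                    "colors must have one RGB triple per point: "
                    f"{self.colors.shape} vs {self.points.shape}"
                )
            if self.colors.min() < 0 or self.colors.max() > 255:
                raise ValueError("color channels must lie in [0, 255]")
            self.colors = self.colors.astype(np.uint8)

    @property
    def count(self) -> int:
        return self.points.shape[0]

    def select(self, index: np.ndarray) -> "PointCloud":
        """Sub-cloud of the rows picked by a boolean mask or index array."""
        colors = self.colors[index] if self.colors is not None else None
        return PointCloud(self.points[index], colors)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.count


@dataclass(frozen=True)
class BoundingVolume:
    """Axis-aligned evaluation box, ``min_corner`` strictly below ``max_corner``."""

    min_corner: Tuple[float, float, float]
    max_corner: Tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_corner, dtype=float)
        hi = np.asarray(self.max_corner, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("bounding volume corners must be 3-vectors")
        if not np.all(lo < hi):
            raise ValueError("min_corner must be strictly less than max_corner on every axis")
        object.__setattr__(self, "min_corner", tuple(lo))
        object.__setattr__(self, "max_corner", tuple(hi))


def load_bounds(path: PathLike) -> BoundingVolume:
    """Read a ``{"min": [x,y,z], "max": [x,y,z]}`` JSON box."""
    with open(path) as fh:
        obj = json.load(fh)
    try:
        return BoundingVolume(tuple(obj["min"]), tuple(obj["max"]))
    except KeyError as exc:
        raise CloudFormatError(f"bounds JSON missing key {exc} in {path}") from exc


# ---------------------------------------------------------------------------
# PLY

_PLY_TYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
    "short": "<i2", "ushort": "<u2", "int": "<i4", "uint": "<u4",
    "int32": "<i4", "uint32": "<u4",
}


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudFormatError(f"{path}: not a PLY file (bad magic {magic!r})")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        props: list[tuple[str, str]] = []
        while True:
            line = fh.readline()
            if not line:
                raise CloudFormatError(f"{path}: unexpected EOF in PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                props = []
                elements.append((tokens[1], int(tokens[2]), props))
            elif tokens[0] == "property":
                if tokens[1] == "list":
                    raise CloudFormatError(f"{path}: PLY list properties unsupported")
                props.append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise CloudFormatError(f"{path}: unsupported PLY format {fmt!r}")
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise CloudFormatError(f"{path}: PLY has no vertex element")
        if elements and elements[0][0] != "vertex":
            raise CloudFormatError(f"{path}: vertex must be the first PLY element")
        _, count, vprops = vertex
        if count == 0:
            raise CloudFormatError(f"{path}: PLY contains zero vertices")
        dtype = np.dtype([(name, _PLY_TYPES[t]) for name, t in vprops])
        if fmt == "ascii":
            rows = []
            for i in range(count):
                line = fh.readline()
                if not line:
                    raise CloudFormatError(f"{path}: vertex {i} missing (truncated file)")
                parts = line.split()
                if len(parts) != len(vprops):
                    raise CloudFormatError(
                        f"{path}: vertex {i} has {len(parts)} fields, expected {len(vprops)}"
                    )
                rows.append(tuple(parts))
            data = np.array(rows, dtype=dtype)
        else:
            raw = fh.read(dtype.itemsize * count)
            if len(raw) != dtype.itemsize * count:
                raise CloudFormatError(f"{path}: truncated PLY binary payload")
            data = np.frombuffer(raw, dtype=dtype)
    for axis in ("x", "y", "z"):
        if axis not in data.dtype.names:
            raise CloudFormatError(f"{path}: PLY vertex lacks '{axis}' property")
    pts = np.stack([data["x"], data["y"], data["z"]], axis=1).astype(np.float64)
    colors = None
    if all(c in data.dtype.names for c in ("red", "green", "blue")):
        colors = np.stack([data["red"], data["green"], data["blue"]], axis=1)
    return PointCloud(pts, colors)


def _write_ply(cloud: PointCloud, path: Path, binary: bool = True) -> None:
    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {cloud.count}",
              "property float x", "property float y", "property float z"]
    if cloud.colors is not None:
        fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    header.append("end_header")
    data = np.empty(cloud.count, dtype=np.dtype(fields))
    pts32 = cloud.points.astype(np.float32)
    data["x"], data["y"], data["z"] = pts32[:, 0], pts32[:, 1], pts32[:, 2]
    if cloud.colors is not None:
        data["red"], data["green"], data["blue"] = (
            cloud.colors[:, 0], cloud.colors[:, 1], cloud.colors[:, 2])
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(data.tobytes())
        else:
            for row in data:
                vals = [repr(float(row[n])) if d.startswith("<f") else str(int(row[n]))
                        for n, d in fields]
                fh.write((" ".join(vals) + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# PCD (v0.7 ASCII)

def _read_pcd(path: Path) -> PointCloud:
    header: dict[str, list[str]] = {}
    data_rows = []
    with open(path) as fh:
        mode = None
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if mode is None:
                key, *vals = line.split()
                header[key.upper()] = vals
                if key.upper() == "DATA":
                    if vals[0] != "ascii":
                        raise CloudFormatError(f"{path}: only ascii PCD supported, got {vals[0]}")
                    mode = "data"
            else:
                data_rows.append((lineno, line.split()))
    if "FIELDS" not in header:
        raise CloudFormatError(f"{path}: PCD header missing FIELDS")
    names = header["FIELDS"]
    if not all(a in names for a in ("x", "y", "z")):
        raise CloudFormatError(f"{path}: PCD fields must include x y z, got {names}")
    count = int(header.get("POINTS", [len(data_rows)])[0])
    if count == 0 or not data_rows:
        raise CloudFormatError(f"{path}: PCD contains zero points")
    if len(data_rows) != count:
        raise CloudFormatError(f"{path}: POINTS={count} but {len(data_rows)} data rows")
    arr = np.empty((count, len(names)), dtype=np.float64)
    for i, (lineno, parts) in enumerate(data_rows):
        if len(parts) != len(names):
            raise CloudFormatError(f"{path}:{lineno}: expected {len(names)} values, got {len(parts)}")
        arr[i] = [float(p) for p in parts]
    pts = arr[:, [names.index("x"), names.index("y"), names.index("z")]]
    colors = None
    if "rgb" in names:
        j = names.index("rgb")
        types = header.get("TYPE", ["F"] * len(names))
        if types[j] == "U":
            packed = arr[:, j].astype(np.uint32)
        else:  # PCL's float-packed convention
            packed = arr[:, j].astype(np.float32).view(np.uint32)
        colors = np.stack([(packed >> 16) & 0xFF, (packed >> 8) & 0xFF, packed & 0xFF], axis=1)
    return PointCloud(pts, colors)


def _write_pcd(cloud: PointCloud, path: Path) -> None:
    has_rgb = cloud.colors is not None
    fields = "x y z rgb" if has_rgb else "x y z"
    n = cloud.count
    lines = [
        "# .PCD v0.7 - Point Cloud Data file format",
        "VERSION 0.7",
        f"FIELDS {fields}",
        "SIZE " + " ".join(["4"] * (4 if has_rgb else 3)),
        "TYPE " + ("F F F U" if has_rgb else "F F F"),
        "COUNT " + ("1 1 1 1" if has_rgb else "1 1 1"),
        f"WIDTH {n}", "HEIGHT 1", "VIEWPOINT 0 0 0 1 0 0 0",
        f"POINTS {n}", "DATA ascii",
    ]
    pts32 = cloud.points.astype(np.float32)
    if has_rgb:
        packed = ((cloud.colors[:, 0].astype(np.uint32) << 16)
                  | (cloud.colors[:, 1].astype(np.uint32) << 8)
                  | cloud.colors[:, 2].astype(np.uint32))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for i in range(n):
            row = " ".join(repr(float(v)) for v in pts32[i])
            if has_rgb:
                row += f" {int(packed[i])}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# XYZ

def _read_xyz(path: Path) -> PointCloud:
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 6):
                raise CloudFormatError(
                    f"{path}:{lineno}: expected 3 (xyz) or 6 (xyzrgb) columns, got {len(parts)}")
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise CloudFormatError(f"{path}:{lineno}: inconsistent column count")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise CloudFormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    if not rows:
        raise CloudFormatError(f"{path}: no points found")
    arr = np.asarray(rows, dtype=np.float64)
    colors = arr[:, 3:6] if arr.shape[1] == 6 else None
    return PointCloud(arr[:, :3], colors)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        for i in range(cloud.count):
            row = " ".join(repr(float(v)) for v in cloud.points[i])
            if cloud.colors is not None:
                row += " " + " ".join(str(int(v)) for v in cloud.colors[i])
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# public API

_EXT_FORMATS = {".ply": "ply", ".pcd": "pcd", ".xyz": "xyz", ".txt": "xyz"}


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    ext = path.suffix.lower()
    if ext not in _EXT_FORMATS:
        raise CloudFormatError(f"cannot infer cloud format from extension {ext!r} ({path})")
    return _EXT_FORMATS[ext]


def load_cloud(path: PathLike, format: str = "auto") -> PointCloud:
    """Load a point cloud from PLY, PCD, or XYZ.

    ``format='auto'`` dispatches on the file extension.  Colors are preserved
    when the file carries them.  Raises :class:`CloudFormatError` on
    unreadable, empty, or malformed files, naming the offending line or
    element where possible.
    """
    path = Path(path)
    if not path.exists():
        raise CloudFormatError(f"cloud file does not exist: {path}")
    fmt = _resolve_format(path, format)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "pcd":
        return _read_pcd(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise CloudFormatError(f"unknown cloud format {fmt!r}")


def write_cloud(cloud: PointCloud, path: PathLike, format: str = "auto",
                ascii_ply: bool = False) -> None:
    """Write a cloud to disk; PLY defaults to binary-little-endian."""
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "ply":
        _write_ply(cloud, path, binary=not ascii_ply)
    elif fmt == "pcd":
        _write_pcd(cloud, path)
    elif fmt == "xyz":
        _write_xyz(cloud, path)
    else:
        raise CloudFormatError(f"unknown cloud format {fmt!r}")


def crop_to_bounds(cloud: PointCloud, bounds: BoundingVolume) -> PointCloud:
    """Keep exactly the points inside the closed axis-aligned box.

    Boundary points are kept; order and colors are preserved.  An empty
    result raises, signaling a misplaced crop box.
    """
    lo = np.asarray(bounds.min_corner)
    hi = np.asarray(bounds.max_corner)
    mask = np.all((cloud.points >= lo) & (cloud.points <= hi), axis=1)
    if not mask.any():
        raise ValueError("crop box contains no points — check the bounding volume placement")
    return cloud.select(mask)


def remove_duplicates(cloud: PointCloud, epsilon: float = 1e-6) -> PointCloud:
    """Drop points within ``epsilon`` of an earlier-kept point.

    Greedy in file order: the first occurrence is retained, later points
    closer than ``epsilon`` to any retained point are dropped.  With
    ``epsilon=0`` only exactly coincident points collapse.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0:
        _, first = np.unique(cloud.points, axis=0, return_index=True)
        keep = np.zeros(cloud.count, dtype=bool)
        keep[first] = True
        return cloud.select(keep)
    tree = cKDTree(cloud.points)
    pairs = tree.query_pairs(epsilon, output_type="ndarray")
    keep = np.ones(cloud.count, dtype=bool)
    if len(pairs):
        # visit close pairs in index order so earlier points win
        order = np.lexsort((pairs.max(axis=1), pairs.min(axis=1)))
        for i, j in pairs[order]:
            a, b = (i, j) if i < j else (j, i)
            if keep[a]:
                keep[b] = False
    return cloud.select(keep)


def remove_statistical_outliers(
    cloud: PointCloud, k_neighbors: int = 20, std_ratio: float = 2.0
) -> Tuple[PointCloud, int]:
    """Statistical outlier removal on the k-NN mean-distance distribution.

    For each point the mean distance to its ``k_neighbors`` nearest
    neighbours is computed; points whose statistic exceeds
    ``global_mean + std_ratio * global_std`` are removed.  Returns the
    retained cloud and the number of points removed.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if cloud.count <= k_neighbors:
        raise ValueError(
            f"cloud too small for k={k_neighbors} neighbours (count={cloud.count})")
    tree = cKDTree(cloud.points)
    # k+1 because each point is its own nearest neighbour at distance 0
    dists, _ = tree.query(cloud.points, k=k_neighbors + 1)
    mean_knn = dists[:, 1:].mean(axis=1)
    cutoff = mean_knn.mean() + std_ratio * mean_knn.std()
    keep = mean_knn <= cutoff
    return cloud.select(keep), int((~keep).sum())
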