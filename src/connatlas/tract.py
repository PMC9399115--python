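"""Streamline geometry primitives.

A *streamline* is an ordered polyline of 3-D points in world millimetres
(RAS orientation).  A *tractogram* bundles many streamlines together with
the voxel grid (dimensions, voxel size and voxel-to-world affine) of the
image they were reconstructed from.

The operations here are the geometric substrate of bundle dissection:
geodesic length, total winding (loop detection), arc-length resampling,
the minimum average direct-flip (MDF) distance used by QuickBundles-style
clustering, lossy polyline compression with a hard error bound, and the
application of affine + displacement-field spatial transforms to points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates


class InvalidStreamlineError(ValueError):
    """Raised for polylines that are not valid streamlines (<2 points,
    non-finite coordinates, wrong shape)."""


def as_streamline(points) -> np.ndarray:
    """Validate and return a streamline as a float (N, 3) array.

    Raises
    ------
    InvalidStreamlineError
        if the input has fewer than 2 points, is not 3-D, or contains
        non-finite coordinates.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidStreamlineError(f"expected (N, 3) points, got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise InvalidStreamlineError("a streamline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise InvalidStreamlineError("streamline contains non-finite coordinates")
    return pts


@dataclass
class Tractogram:
    """A collection of streamlines plus the reference voxel grid.

    Parameters
    ----------
    streamlines : list of (N, 3) arrays, world mm (RAS)
    affine : (4, 4) voxel-to-world matrix; must be invertible
    grid_dim : three positive integers, grid shape
    grid_voxsize : three positive voxel edge lengths in mm
    """

    streamlines: list[np.ndarray]
    affine: np.ndarray
    grid_dim: tuple[int, int, int]
    grid_voxsize: tuple[float, float, float]

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        self.grid_dim = tuple(int(d) for d in self.grid_dim)
        self.grid_voxsize = tuple(float(v) for v in self.grid_voxsize)
        if any(d <= 0 for d in self.grid_dim):
            raise ValueError("grid_dim must be positive")
        if any(v <= 0 for v in self.grid_voxsize):
            raise ValueError("grid_voxsize must be positive")
        self.streamlines = [as_streamline(s) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class SpatialTransform:
    """An affine map optionally composed with a displacement field.

    Points map as ``p' = A @ p + D(A @ p)`` where ``D`` is a 3-vector
    field defined on its own grid (mm displacements, trilinear
    interpolation).  ``D`` is identically zero when no field is given.
    """

    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    displacement: np.ndarray | None = None      # (X, Y, Z, 3) mm
    displacement_affine: np.ndarray | None = None

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.displacement is not None:
            self.displacement = np.asarray(self.displacement, dtype=float)
            if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
                raise ValueError("displacement field must have shape (X, Y, Z, 3)")
            if self.displacement_affine is None:
                raise ValueError("a displacement field needs its own affine")
            self.displacement_affine = np.asarray(self.displacement_affine, dtype=float)


def streamline_length(points) -> float:
    """Geodesic (polyline) length in mm: sum of Euclidean segment lengths."""
    pts = as_streamline(points)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def total_winding(points) -> float:
    """Total unsigned turning of the polyline in degrees.

    The sum of the absolute angles between consecutive segment directions.
    Zero-length segments are skipped.  Streamlines with fewer than three
    effective points turn by 0 degrees.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidStreamlineError(f"expected (N, 3) points, got shape {pts.shape}")
    if pts.shape[0] < 3:
        return 0.0
    seg = np.diff(pts, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    seg = seg[norms > 0]
    if seg.shape[0] < 2:
        return 0.0
    u = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    cosang = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)).sum())


def is_loop(points, max_winding_deg: float = 360.0) -> bool:
    """True when the streamline winds strictly more than ``max_winding_deg``."""
    return total_winding(points) > max_winding_deg


def resample_streamline(points, n: int) -> np.ndarray:
    """Resample to ``n`` points equally spaced in arc length.

    Endpoints are preserved exactly.  A fully degenerate streamline (all
    points identical) resamples to ``n`` copies of that point.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    pts = as_streamline(points)
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total == 0.0:
        return np.repeat(pts[:1], n, axis=0)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(t, cum, pts[:, k])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def mdf_distance(a, b, n: int = 12) -> float:
    """Minimum average direct-flip distance between two streamlines.

    Both streamlines are resampled to ``n`` points; the distance is the
    smaller of the mean point-wise Euclidean distance taken in direct and
    in reversed order.  Symmetric, non-negative, zero for identical or
    exactly reversed streamlines.
    """
    ra = resample_streamline(a, n)
    rb = resample_streamline(b, n)
    direct = float(np.linalg.norm(ra - rb, axis=1).mean())
    flipped = float(np.linalg.norm(ra - rb[::-1], axis=1).mean())
    return min(direct, flipped)


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from points ``p`` (N, 3) to the segment [a, b]."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(p - a, axis=1)
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def compress_streamline(points, max_error: float = 0.2) -> np.ndarray:
    """Lossy polyline compression with a hard point-to-chord error bound.

    Keeps a subset of the original points, always including both
    endpoints, such that every removed point lies within ``max_error``
    mm of the retained polyline (Ramer-Douglas-Peucker recursion: a point
    is only dropped against a chord that survives into the output).
    Default bound 0.2 mm.
    """
    if max_error <= 0:
        raise ValueError("max_error must be > 0")
    pts = as_streamline(points)
    n = pts.shape[0]
    if n == 2:
        return pts.copy()
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        inner = pts[i + 1 : j]
        d = _point_segment_distance(inner, pts[i], pts[j])
        kmax = int(np.argmax(d))
        if d[kmax] > max_error:
            split = i + 1 + kmax
            keep[split] = True
            stack.append((i, split))
            stack.append((split, j))
    return pts[keep]


def transform_points(
    t: Tractogram, xf: SpatialTransform, *, outside: str = "error"
) -> Tractogram:
    """Apply a spatial transform to every point of a tractogram.

    Mapping: ``p' = A p + D(A p)`` with trilinear interpolation of the
    displacement field.  ``outside`` controls points falling outside the
    field's support: ``"error"`` (default) raises, ``"zero"`` applies a
    zero displacement there.

    The output has the same streamline count and per-streamline point
    counts; only coordinates change.  Grid metadata is carried over.
    """
    if outside not in ("error", "zero"):
        raise ValueError("outside must be 'error' or 'zero'")
    A = xf.affine
    out = []
    for s in t.streamlines:
        p = s @ A[:3, :3].T + A[:3, 3]
        if xf.displacement is not None:
            inv = np.linalg.inv(xf.displacement_affine)
            vox = p @ inv[:3, :3].T + inv[:3, 3]
            shape = np.array(xf.displacement.shape[:3])
            inside = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
            if not np.all(inside) and outside == "error":
                raise ValueError(
                    f"{int((~inside).sum())} point(s) fall outside the "
                    "displacement-field support (pass outside='zero' to "
                    "apply zero displacement there)"
                )
            disp = np.zeros_like(p)
            if np.any(inside):
                coords = vox[inside].T
                for k in range(3):
                    disp[inside, k] = map_coordinates(
                        xf.displacement[..., k], coords, order=1, mode="nearest"
                    )
            p = p + disp
        out.append(p)
    return Tractogram(out, t.affine, t.grid_dim, t.grid_voxsize)


# ---------------------------------------------------------------------------
# Tractogram containers: TRK/TCK via nibabel, plus a plain-text fallback.
# ---------------------------------------------------------------------------

def save_tractogram(t: Tractogram, path) -> None:
    """Write a tractogram.  Format chosen by extension: ``.trk``, ``.tck``
    or the plain-text fallback (any other extension, documented below)."""
    path = Path(path)
    if path.suffix in (".trk", ".tck"):
        import nibabel as nib
        from nibabel.streamlines import Tractogram as NibTractogram

        header = {
            "dimensions": np.asarray(t.grid_dim, dtype=np.int16),
            "voxel_sizes": np.asarray(t.grid_voxsize, dtype=np.float32),
            "voxel_to_rasmm": t.affine.astype(np.float32),
        }
        nt = NibTractogram(t.streamlines, affine_to_rasmm=np.eye(4))
        nib.streamlines.save(nt, str(path), header=header if path.suffix == ".trk" else None)
    else:
        _save_text(t, path)


def load_tractogram(path) -> Tractogram:
    path = Path(path)
    if path.suffix in (".trk", ".tck"):
        import nibabel as nib

        f = nib.streamlines.load(str(path))
        hdr = f.header
        if path.suffix == ".trk":
            dim = tuple(int(d) for d in hdr["dimensions"])
            voxsize = tuple(float(v) for v in hdr["voxel_sizes"])
            affine = np.asarray(hdr["voxel_to_rasmm"], dtype=float)
        else:  # TCK carries no grid; assume unit 1 mm grid
            dim, voxsize, affine = (1, 1, 1), (1.0, 1.0, 1.0), np.eye(4)
        return Tractogram(
            [np.asarray(s, dtype=float) for s in f.tractogram.streamlines],
            affine, dim, voxsize,
        )
    return _load_text(path)


def _save_text(t: Tractogram, path) -> None:
    """Plain-text container: a commented header with the grid (dim,
    voxsize, affine rows), then one ``x y z`` point per line, with a
    single ``#streamline`` line delimiting consecutive streamlines."""
    with open(path, "w") as fh:
        fh.write("# connatlas tractogram v1\n")
        fh.write("# dim " + " ".join(str(d) for d in t.grid_dim) + "\n")
        fh.write("# voxsize " + " ".join(repr(float(v)) for v in t.grid_voxsize) + "\n")
        for row in t.affine:
            fh.write("# affine " + " ".join(repr(float(v)) for v in row) + "\n")
        for k, s in enumerate(t.streamlines):
            if k:
                fh.write("#streamline\n")
            for p in s:
                fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")


def _load_text(path) -> Tractogram:
    dim = None
    voxsize = None
    affine_rows: list[list[float]] = []
    streamlines: list[np.ndarray] = []
    current: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("dim "):
                    dim = tuple(int(v) for v in body.split()[1:4])
                elif body.startswith("voxsize "):
                    voxsize = tuple(float(v) for v in body.split()[1:4])
                elif body.startswith("affine "):
                    affine_rows.append([float(v) for v in body.split()[1:5]])
                elif body == "streamline":
                    if current:
                        streamlines.append(np.array(current))
                        current = []
                continue
            current.append([float(v) for v in line.split()])
    if current:
        streamlines.append(np.array(current))
    if dim is None or voxsize is None or len(affine_rows) != 4:
        raise ValueError(f"{path}: missing or malformed tractogram header")
    return Tractogram(streamlines, np.array(affine_rows), dim, voxsize)
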