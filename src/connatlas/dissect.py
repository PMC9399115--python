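"""Tractogram dissection: whole-brain streamlines -> region-pair bundles.

Given a labelled gray-matter parcellation (optionally dilated toward the
white matter) and a tractogram, streamlines are assigned to the unordered
pair of regions containing their endpoints.  Each region-pair bundle is
then cleaned: loops (total winding > 360 degrees) are removed, and
spatial outliers are rejected with a QuickBundles-style cluster tree.
The result is a per-subject bundle set plus number-of-streamlines (NOS)
and mean-length connectivity matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .tract import (
    Tractogram,
    is_loop,
    mdf_distance,
    resample_streamline,
    streamline_length,
)

logger = logging.getLogger(__name__)

LABEL_TABLE_COLUMNS = ["code", "name", "hemisphere", "R", "G", "B", "x", "y", "z"]


@dataclass
class LabelVolume:
    """An integer parcellation volume with its label table.

    ``labels`` is a 3-D integer grid (0 = background); ``table`` is a
    DataFrame with columns code, name, hemisphere (L/R/M), R, G, B and
    the region centroid x, y, z in mm.  Every nonzero voxel value must
    appear in the table and codes must be unique.
    """

    labels: np.ndarray
    affine: np.ndarray
    table: pd.DataFrame

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be a 3-D integer grid")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        missing = set(LABEL_TABLE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"label table missing columns: {sorted(missing)}")
        codes = self.table["code"].to_numpy()
        if len(np.unique(codes)) != len(codes):
            raise ValueError("label codes must be unique")
        if np.any(codes <= 0):
            raise ValueError("label codes must be positive (0 is background)")
        present = np.unique(self.labels)
        present = present[present != 0]
        unknown = set(present.tolist()) - set(codes.tolist())
        if unknown:
            raise ValueError(f"voxel labels missing from table: {sorted(unknown)}")

    @property
    def codes(self) -> np.ndarray:
        return self.table["code"].to_numpy()

    def hemisphere_of(self, code: int) -> str:
        row = self.table.loc[self.table["code"] == code]
        if row.empty:
            raise KeyError(f"unknown region code {code}")
        return str(row["hemisphere"].iloc[0])

    def save_table(self, path) -> None:
        self.table[LABEL_TABLE_COLUMNS].to_csv(path, index=False)

    @staticmethod
    def load_table(path) -> pd.DataFrame:
        return pd.read_csv(path)


@dataclass
class BundleSet:
    """Cleaned region-pair bundles at one parcellation scale.

    ``pair_map`` maps the unordered pair ``(i, j)`` with ``i < j`` to the
    list of streamlines of the bundle.
    """

    scale_id: int
    pair_map: dict[tuple[int, int], list[np.ndarray]] = field(default_factory=dict)

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pair_map)

    def n_streamlines(self) -> int:
        return sum(len(v) for v in self.pair_map.values())


@dataclass
class SubjectConnectome:
    """Per-subject NOS and mean-length matrices over the region codes."""

    codes: np.ndarray
    nos: np.ndarray
    length: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        self.nos = np.asarray(self.nos, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        n = len(self.codes)
        for name, m in (("nos", self.nos), ("length", self.length)):
            if m.shape != (n, n):
                raise ValueError(f"{name} matrix must be {n}x{n}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} matrix must be symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{name} matrix must have a zero diagonal")

    def index_of(self, code: int) -> int:
        idx = np.flatnonzero(self.codes == code)
        if idx.size == 0:
            raise KeyError(f"unknown region code {code}")
        return int(idx[0])


def dilate_parcellation(
    p: LabelVolume, radius: float, wm_mask: np.ndarray, voxsize=None
) -> LabelVolume:
    """Grow labels into unlabeled white-matter voxels within ``radius`` mm.

    Originally labelled voxels never change.  An unlabeled voxel inside
    ``wm_mask`` takes the label of the nearest labelled voxel (Euclidean
    distance between voxel centers, in mm) when that distance is at most
    ``radius``; ties go to the lower region code.  Nothing outside the
    WM mask gains a label.
    """
    wm_mask = np.asarray(wm_mask).astype(bool)
    if wm_mask.shape != p.labels.shape:
        raise ValueError("wm_mask grid does not match the parcellation grid")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return LabelVolume(p.labels.copy(), p.affine, p.table.copy())
    if voxsize is None:
        voxsize = np.linalg.norm(p.affine[:3, :3], axis=0)
    voxsize = np.asarray(voxsize, dtype=float)

    codes = np.sort(p.codes)  # ascending: argmin tie -> lower code
    dist = np.full(p.labels.shape, np.inf)
    winner = np.zeros(p.labels.shape, dtype=p.labels.dtype)
    for code in codes:
        d = ndimage.distance_transform_edt(p.labels != code, sampling=voxsize)
        better = d < dist  # strict: first (lowest) code keeps ties
        dist[better] = d[better]
        winner[better] = code

    out = p.labels.copy()
    grow = (p.labels == 0) & wm_mask & (dist <= radius)
    out[grow] = winner[grow]
    return LabelVolume(out, p.affine, p.table.copy())


def assign_endpoints(points, p: LabelVolume) -> tuple[int, int] | None:
    """Region pair of a streamline, from the voxels containing its endpoints.

    Returns the sorted pair ``(i, j)`` when both endpoint voxels carry
    distinct nonzero labels; ``None`` (unassigned) when either endpoint
    lies in background or outside the grid, or when both labels agree
    (self-connections are excluded).
    """
    pts = np.asarray(points, dtype=float)
    inv = np.linalg.inv(p.affine)
    ends = pts[[0, -1]] @ inv[:3, :3].T + inv[:3, 3]
    vox = np.rint(ends).astype(int)
    shape = np.array(p.labels.shape)
    labels = []
    for v in vox:
        if np.any(v < 0) or np.any(v >= shape):
            logger.warning("streamline endpoint %s outside the grid", v)
            return None
        labels.append(int(p.labels[tuple(v)]))
    i, j = labels
    if i == 0 or j == 0 or i == j:
        return None
    return (i, j) if i < j else (j, i)


def quickbundles(
    bundle: list[np.ndarray], threshold: float, n_points: int = 12
) -> tuple[list[list[int]], list[np.ndarray]]:
    """Single-pass streamline clustering (QuickBundles scheme).

    Each streamline joins the first existing cluster whose centroid lies
    within ``threshold`` (MDF, mm), else founds a new cluster.  Cluster
    centroids are the running mean of flip-aligned streamlines resampled
    to ``n_points``.

    Returns ``(clusters, centroids)`` where ``clusters`` is a list of
    index lists partitioning the input and ``centroids`` the matching
    centroid streamlines.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    clusters: list[list[int]] = []
    centroids: list[np.ndarray] = []
    for idx, s in enumerate(bundle):
        rs = resample_streamline(s, n_points)
        placed = False
        for c, centroid in enumerate(centroids):
            direct = float(np.linalg.norm(rs - centroid, axis=1).mean())
            flipped = float(np.linalg.norm(rs[::-1] - centroid, axis=1).mean())
            if min(direct, flipped) < threshold:
                aligned = rs if direct <= flipped else rs[::-1]
                k = len(clusters[c])
                centroids[c] = (centroid * k + aligned) / (k + 1)
                clusters[c].append(idx)
                placed = True
                break
        if not placed:
            clusters.append([idx])
            centroids.append(rs.copy())
    return clusters, centroids


def tree_length_scores(
    bundle: list[np.ndarray],
    base_threshold: float = 10.0,
    n_levels: int = 3,
    n_points: int = 12,
) -> np.ndarray:
    """Normalised cluster-tree membership score per streamline.

    The bundle is clustered at the decreasing threshold sequence
    ``t, t/2, t/4, ...`` (``n_levels`` levels).  A streamline's score is
    the mean over levels of the size fraction of its cluster.  Coherent
    streamlines sit in large clusters at every level (score near 1);
    isolated outliers found singleton clusters (score near 1/n).
    """
    n = len(bundle)
    if n == 0:
        return np.zeros(0)
    scores = np.zeros(n)
    for level in range(n_levels):
        thr = base_threshold / (2 ** level)
        clusters, _ = quickbundles(bundle, thr, n_points=n_points)
        for members in clusters:
            frac = len(members) / n
            for idx in members:
                scores[idx] += frac
    return scores / n_levels


def clean_bundle(
    bundle: list[np.ndarray],
    tree_threshold: float = 0.2,
    *,
    base_threshold: float = 10.0,
    max_winding: float = 360.0,
) -> list[np.ndarray]:
    """Remove loops and spatial outliers from a region-pair bundle.

    Stage 1 drops streamlines winding more than ``max_winding`` degrees.
    Stage 2 drops streamlines whose cluster-tree score (see
    :func:`tree_length_scores`) falls below ``tree_threshold``; bundles
    of two or fewer streamlines skip stage 2.  The output is always a
    subset of the input.
    """
    if not 0 < tree_threshold < 1:
        raise ValueError("tree_threshold must be in (0, 1)")
    kept = [s for s in bundle if not is_loop(s, max_winding)]
    if len(kept) <= 2:
        return kept
    scores = tree_length_scores(kept, base_threshold=base_threshold)
    return [s for s, sc in zip(kept, scores) if sc >= tree_threshold]


def extract_bundles(
    t: Tractogram,
    p: LabelVolume,
    min_len: float = 20.0,
    max_len: float = 200.0,
    *,
    scale_id: int = 1,
    clean: bool = True,
    tree_threshold: float = 0.2,
) -> tuple[BundleSet, SubjectConnectome]:
    """Dissect a tractogram into cleaned region-pair bundles.

    Streamlines outside the inclusive length band ``[min_len, max_len]``
    mm or failing endpoint assignment are discarded; each surviving
    region-pair bundle is cleaned (loops + outliers) unless
    ``clean=False``.  NOS and mean-length matrices are computed from the
    bundles *after* cleaning.
    """
    raw: dict[tuple[int, int], list[np.ndarray]] = {}
    for s in t.streamlines:
        length = streamline_length(s)
        if length < min_len or length > max_len:
            continue
        pair = assign_endpoints(s, p)
        if pair is None:
            continue
        raw.setdefault(pair, []).append(s)

    pair_map = {}
    for pair, streams in sorted(raw.items()):
        cleaned = clean_bundle(streams, tree_threshold) if clean else streams
        if cleaned:
            pair_map[pair] = cleaned
    bundles = BundleSet(scale_id=scale_id, pair_map=pair_map)

    codes = np.sort(p.codes)
    n = len(codes)
    code_index = {int(c): k for k, c in enumerate(codes)}
    nos = np.zeros((n, n))
    length = np.zeros((n, n))
    for (i, j), streams in pair_map.items():
        a, b = code_index[i], code_index[j]
        nos[a, b] = nos[b, a] = len(streams)
        mean_len = float(np.mean([streamline_length(s) for s in streams]))
        length[a, b] = length[b, a] = mean_len
    return bundles, SubjectConnectome(codes=codes, nos=nos, length=length)


def connectome_to_frame(c: SubjectConnectome, which: str = "nos") -> pd.DataFrame:
    """Matrix as a DataFrame with region-code headers (CSV-ready)."""
    m = getattr(c, which)
    return pd.DataFrame(m, index=c.codes, columns=c.codes)
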