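"""Group atlas construction from per-subject bundles.

Per-subject bundles are rasterised into tract density images (TDI); a
bundle's spatial probabilistic anatomical map (SPAM) counts, per voxel,
the subjects whose bundle traverses it (binarised TDIs summed across
subjects; probability = count / n_subjects).  Group matrices record
inter-subject consistency, mean streamline count and mean geodesic
length per region pair.  A distance-dependent consensus threshold then
fixes the bundle list: connections are retained so that the atlas
matches the average subject's connection density separately for intra-
and inter-hemispheric connections and within bins of connection length,
preferring the most consistent candidates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .dissect import SubjectConnectome

logger = logging.getLogger(__name__)


def connectivity_density(n_gm: int, n_bundle: int) -> float:
    """Whole-brain connectivity density, percent: 100 * n_bundle / C(n_gm, 2)."""
    if n_gm < 2:
        raise ValueError("need at least 2 regions")
    return 100.0 * n_bundle / (n_gm * (n_gm - 1) / 2)


def multiscale_region_count(
    n_cortical: int,
    subcortical_per_hemisphere: int = 6,
    thalamic_nuclei_per_hemisphere: int = 7,
    n_brainstem: int = 1,
) -> int:
    """Total gray-matter region count at one parcellation scale.

    Cortical regions plus bilateral subcortical structures (caudate,
    putamen, accumbens, pallidum, amygdala, hippocampus), bilateral
    thalamic nuclei, and the brainstem.
    """
    return (
        n_cortical
        + 2 * subcortical_per_hemisphere
        + 2 * thalamic_nuclei_per_hemisphere
        + n_brainstem
    )


@dataclass
class TDIVolume:
    """Tract density image of one subject's bundle: per-voxel count of
    streamlines traversing the voxel (each streamline counted once)."""

    counts: np.ndarray
    affine: np.ndarray
    pair: tuple[int, int]
    subject_id: int | str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("TDI counts must be non-negative")


@dataclass
class SPAM:
    """Sparse probabilistic map of one bundle across subjects.

    ``voxels`` is an (N, 3) integer index array, ``counts`` the matching
    per-voxel number of subjects (1..nsubjects) whose bundle traverses
    the voxel.  Probability = counts / nsubjects.
    """

    pair: tuple[int, int]
    voxels: np.ndarray
    counts: np.ndarray
    nsubjects: int

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)
        self.counts = np.asarray(self.counts, dtype=np.int64).reshape(-1)
        if self.voxels.shape[0] != self.counts.shape[0]:
            raise ValueError("voxels and counts length mismatch")
        if self.counts.size and (self.counts.min() < 1 or self.counts.max() > self.nsubjects):
            raise ValueError("SPAM counts must lie in 1..nsubjects")
        keys = [tuple(v) for v in self.voxels]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate voxels in SPAM")

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.nsubjects


@dataclass
class GroupMatrices:
    """Group-level connection matrices over a fixed region-code order."""

    codes: np.ndarray
    consistency: np.ndarray   # subjects with >=1 streamline
    numbStlines: np.ndarray   # mean NOS over all subjects
    length: np.ndarray        # mean length over subjects with the connection
    nsubjects: int

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        self.consistency = np.asarray(self.consistency)
        self.numbStlines = np.asarray(self.numbStlines, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        n = len(self.codes)
        for name in ("consistency", "numbStlines", "length"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
        if self.consistency.size and self.consistency.max(initial=0) > self.nsubjects:
            raise ValueError("consistency cannot exceed nsubjects")

    def index_of(self, code: int) -> int:
        idx = np.flatnonzero(self.codes == code)
        if idx.size == 0:
            raise KeyError(f"unknown region code {code}")
        return int(idx[0])


@dataclass
class AtlasHeader:
    """Grid and region metadata of an atlas (HDF5 ``header`` group)."""

    nsubjects: int
    dim: tuple[int, int, int]
    voxsize: tuple[float, float, float]
    affine: np.ndarray
    gmregions: list[str]
    gmcodes: np.ndarray
    gmcolors: np.ndarray
    gmcoords: np.ndarray

    def __post_init__(self):
        self.dim = tuple(int(d) for d in self.dim)
        self.voxsize = tuple(float(v) for v in self.voxsize)
        if any(d <= 0 for d in self.dim) or any(v <= 0 for v in self.voxsize):
            raise ValueError("dim and voxsize must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        self.gmregions = [str(r) for r in self.gmregions]
        self.gmcodes = np.asarray(self.gmcodes, dtype=np.int64)
        self.gmcolors = np.asarray(self.gmcolors, dtype=np.int64).reshape(-1, 3)
        self.gmcoords = np.asarray(self.gmcoords, dtype=float).reshape(-1, 3)
        n = len(self.gmregions)
        if not (len(self.gmcodes) == len(self.gmcolors) == len(self.gmcoords) == n):
            raise ValueError("header GM arrays must all have the same length")
        if len(np.unique(self.gmcodes)) != n:
            raise ValueError("gmcodes must be unique")


@dataclass
class AtlasModel:
    """A complete bundle atlas: header + group matrices + retained SPAMs."""

    header: AtlasHeader
    matrices: GroupMatrices
    spams: dict[tuple[int, int], SPAM] = field(default_factory=dict)

    def __post_init__(self):
        codes = set(int(c) for c in self.header.gmcodes)
        for (i, j) in self.spams:
            if i not in codes or j not in codes:
                raise ValueError(f"SPAM pair ({i}, {j}) not in header region codes")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.spams)

    @property
    def n_bundles(self) -> int:
        return len(self.spams)

    @property
    def nsubjects(self) -> int:
        return self.header.nsubjects


def compute_tdi(
    bundle: list[np.ndarray],
    dim: tuple[int, int, int],
    affine: np.ndarray,
    voxsize=None,
    pair: tuple[int, int] = (0, 0),
    subject_id=None,
) -> TDIVolume:
    """Rasterise a bundle into a tract density image.

    Each streamline increments each voxel it traverses at most once.
    Traversal is exact: every segment is marched through the voxel grid
    by its half-integer plane crossings (no voxel can be skipped, however
    briefly the polyline clips it).  Samples falling outside the grid
    are ignored (logged).
    """
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    counts = np.zeros(tuple(int(d) for d in dim), dtype=np.int64)
    shape = np.array(counts.shape)
    clipped = 0
    for s in bundle:
        pts = np.asarray(s, dtype=float) @ inv[:3, :3].T + inv[:3, 3]
        vox = _traverse_voxels(pts)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        clipped += int((~inside).sum())
        vox = vox[inside]
        if vox.size:
            counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    if clipped:
        logger.info("compute_tdi: ignored %d out-of-grid voxel hits", clipped)
    return TDIVolume(counts=counts, affine=affine, pair=pair, subject_id=subject_id)


def _traverse_voxels(pts: np.ndarray) -> np.ndarray:
    """Unique voxel indices traversed by a polyline in voxel coordinates
    (voxel i spans [i-0.5, i+0.5) along each axis)."""
    seen: set[tuple[int, int, int]] = set()
    for a, b in zip(pts[:-1], pts[1:]):
        d = b - a
        ts = [0.0, 1.0]
        for k in range(3):
            if d[k] == 0.0:
                continue
            lo = math.floor(min(a[k], b[k]) + 0.5)
            hi = math.floor(max(a[k], b[k]) + 0.5)
            for m in range(lo, hi):
                ts.append((m + 0.5 - a[k]) / d[k])
        ts = sorted(t for t in ts if 0.0 <= t <= 1.0)
        for t0, t1 in zip(ts[:-1], ts[1:]):
            mid = a + 0.5 * (t0 + t1) * d
            seen.add(tuple(int(math.floor(v + 0.5)) for v in mid))
        seen.add(tuple(int(math.floor(v + 0.5)) for v in b))
    return np.array(sorted(seen), dtype=np.int64).reshape(-1, 3)


def build_spam(tdis: list[TDIVolume], nsubjects: int | None = None) -> tuple[SPAM, np.ndarray]:
    """Aggregate per-subject TDIs of one bundle into a SPAM and mean TDI.

    The SPAM counts, per voxel, the subjects whose (binarised at >=1
    streamline) TDI covers the voxel; only voxels covered by at least
    one subject are stored.  The mean TDI averages the raw counts over
    all ``nsubjects`` (subjects without the bundle contribute zeros).
    """
    if not tdis:
        raise ValueError("need at least one TDI")
    shape = tdis[0].counts.shape
    pair = tdis[0].pair
    for t in tdis:
        if t.counts.shape != shape or not np.allclose(t.affine, tdis[0].affine):
            raise ValueError("all TDIs must share one grid")
    S = nsubjects if nsubjects is not None else len(tdis)
    if S < 1 or S < len(tdis):
        raise ValueError("nsubjects must be >= number of TDIs")
    subject_sum = np.zeros(shape, dtype=np.int64)
    raw_sum = np.zeros(shape, dtype=float)
    for t in tdis:
        subject_sum += (t.counts >= 1)
        raw_sum += t.counts
    idx = np.argwhere(subject_sum >= 1)
    counts = subject_sum[idx[:, 0], idx[:, 1], idx[:, 2]]
    spam = SPAM(pair=pair, voxels=idx, counts=counts, nsubjects=S)
    return spam, raw_sum / S


def group_connectivity(subject_connectomes: list[SubjectConnectome]) -> GroupMatrices:
    """Aggregate per-subject NOS/length matrices into group matrices.

    consistency(i,j) = number of subjects with nos > 0; numbStlines =
    mean NOS over *all* subjects; length = mean of per-subject mean
    lengths over the subjects that have the connection (0 where none do).
    """
    if not subject_connectomes:
        raise ValueError("need at least one subject connectome")
    codes = subject_connectomes[0].codes
    for c in subject_connectomes[1:]:
        if not np.array_equal(c.codes, codes):
            raise ValueError("subject connectomes have inconsistent region sets")
    S = len(subject_connectomes)
    nos_stack = np.stack([c.nos for c in subject_connectomes])
    len_stack = np.stack([c.length for c in subject_connectomes])
    present = nos_stack > 0
    consistency = present.sum(axis=0).astype(np.int64)
    numb = nos_stack.mean(axis=0)
    with np.errstate(invalid="ignore"):
        length = np.where(
            consistency > 0,
            (len_stack * present).sum(axis=0) / np.maximum(consistency, 1),
            0.0,
        )
    return GroupMatrices(
        codes=codes, consistency=consistency, numbStlines=numb,
        length=length, nsubjects=S,
    )


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Interior quantile edges producing up to ``n_bins`` equal-count bins."""
    qs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    return np.quantile(values, qs) if qs.size else np.zeros(0)


def consensus_threshold(
    subject_connectomes: list[SubjectConnectome],
    group: GroupMatrices,
    hemispheres: dict[int, str],
    c_min: float = 0.0,
    n_bins: int = 10,
) -> set[tuple[int, int]]:
    """Distance-dependent consensus selection of the atlas bundle list.

    Keeps a group-representative set of connections whose density matches
    the average subject, separately for intra-hemispheric (both regions
    L or both R) and inter-hemispheric connections (everything else,
    including midline M regions), and within equal-count bins of group
    mean connection length:

    1. candidates: pairs observed in at least ``ceil(c_min * S)``
       subjects (and at least one subject);
    2. candidates split by hemisphere class;
    3. per class, candidates partitioned into ``n_bins`` quantile bins
       of group mean length;
    4. per bin, the target is the rounded mean over subjects of how many
       of that subject's existing connections of the class fall in the
       bin (by group mean length);
    5. the ``target`` most consistent candidates are kept per bin
       (ties: higher consistency, then higher mean NOS, then
       lexicographic pair), capped at the bin's candidate count.

    Deterministic for fixed inputs.
    """
    if not 0.0 <= c_min <= 1.0:
        raise ValueError("c_min must lie in [0, 1]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    S = group.nsubjects
    if S == 0 or not subject_connectomes:
        raise ValueError("need at least one subject")
    codes = group.codes
    n = len(codes)
    min_subjects = max(math.ceil(c_min * S), 1)

    def hemi_class(i_code: int, j_code: int) -> str:
        hi, hj = hemispheres.get(int(i_code)), hemispheres.get(int(j_code))
        if hi == hj and hi in ("L", "R"):
            return "intra"
        return "inter"

    # all observed pairs with their class and group length
    iu, ju = np.triu_indices(n, k=1)
    observed = group.consistency[iu, ju] >= 1
    pair_idx = list(zip(iu[observed].tolist(), ju[observed].tolist()))
    classes = {p: hemi_class(codes[p[0]], codes[p[1]]) for p in pair_idx}

    retained: set[tuple[int, int]] = set()
    for cls in ("intra", "inter"):
        cls_pairs = [p for p in pair_idx if classes[p] == cls]
        candidates = [
            p for p in cls_pairs if group.consistency[p[0], p[1]] >= min_subjects
        ]
        if not candidates:
            continue
        cand_len = np.array([group.length[p[0], p[1]] for p in candidates])
        edges = _quantile_bins(cand_len, n_bins)
        cand_bin = np.searchsorted(edges, cand_len, side="right")

        # per-subject class-connection lengths, binned by the same edges
        n_eff_bins = len(edges) + 1
        subj_counts = np.zeros((S, n_eff_bins))
        cls_all_len = np.array([group.length[p[0], p[1]] for p in cls_pairs])
        cls_rows = np.array([p[0] for p in cls_pairs], dtype=int)
        cls_cols = np.array([p[1] for p in cls_pairs], dtype=int)
        for s_idx, sc in enumerate(subject_connectomes):
            have = sc.nos[cls_rows, cls_cols] > 0
            bins = np.searchsorted(edges, cls_all_len[have], side="right")
            for b in bins:
                subj_counts[s_idx, b] += 1

        targets = np.rint(subj_counts.mean(axis=0)).astype(int)
        for b in range(n_eff_bins):
            members = [p for p, pb in zip(candidates, cand_bin) if pb == b]
            if not members:
                continue
            members.sort(
                key=lambda p: (
                    -group.consistency[p[0], p[1]],
                    -group.numbStlines[p[0], p[1]],
                    p,
                )
            )
            keep = min(int(targets[b]), len(members))
            for p in members[:keep]:
                retained.add((int(codes[p[0]]), int(codes[p[1]])))
    return retained


def assemble_atlas(
    header: AtlasHeader,
    group: GroupMatrices,
    spams: dict[tuple[int, int], SPAM],
    retained: set[tuple[int, int]],
) -> AtlasModel:
    """Build the final atlas, keeping only SPAMs of retained pairs.

    Raises if a retained pair has no SPAM.
    """
    kept = {}
    for pair in sorted(retained):
        if pair not in spams:
            raise ValueError(f"missing SPAM for retained pair {pair}")
        kept[pair] = spams[pair]
    return AtlasModel(header=header, matrices=group, spams=kept)
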