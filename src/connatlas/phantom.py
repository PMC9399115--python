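"""Seeded synthetic phantom: parcellations, tractograms, scalar maps.

The phantom emulates the inputs of the atlas pipeline with known ground
truth: a hemisphere-structured block parcellation (left for voxels with
x below the grid midline, right otherwise), multi-subject tractograms in
which each ground-truth connection appears with a per-edge presence
probability and a Poisson streamline count, per-edge scalar values
painted onto a background map, and spherical lesion masks.  Streamlines
are quadratic arcs with a perpendicular apex offset (curved, but winding
well below 360 degrees) plus Gaussian spatial jitter; explicit options
inject looping and off-axis outlier streamlines to exercise the bundle
cleaning.  Everything is reproducible: per-subject random streams are
derived from the master seed with ``SeedSequence(seed,
spawn_key=(subject_index, purpose))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .apply import ScalarVolume
from .dissect import LABEL_TABLE_COLUMNS, LabelVolume
from .tract import Tractogram

_PALETTE = [
    (230, 25, 75), (0, 92, 230), (60, 180, 75), (255, 225, 25),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (210, 245, 60), (170, 110, 40),
]


@dataclass
class PhantomEdge:
    """One ground-truth connection of the phantom.

    ``apex_offset`` (signed, mm) bows the arc along +z; ``anchor_offset``
    (signed, mm) shifts both endpoint anchors off the region center along
    z.  The default layout gives intra- and inter-hemispheric edges
    opposite signs so that arcs of edges sharing a region run in
    separate spatial lanes and their atlas supports stay disjoint.
    """

    i: int
    j: int
    presence_prob: float = 1.0   # pi_e: probability a subject has the edge
    rate: float = 5.0            # lambda_e: Poisson streamline count (min 1)
    scalar: float = 0.5          # v_e painted on the bundle support
    apex_offset: float = 6.0     # mm, signed perpendicular arc bump
    anchor_offset: float = 0.0   # mm, signed z-shift of the endpoint anchors

    def __post_init__(self):
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must lie in [0, 1]")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.i == self.j:
            raise ValueError("self-connections are not allowed")
        if self.i > self.j:
            self.i, self.j = self.j, self.i


@dataclass
class PhantomSpec:
    """Study conditions of the synthetic phantom.

    Defaults: a 48 mm cubic 1 mm grid, two block regions per hemisphere,
    four ground-truth edges (one intra-hemispheric pair per hemisphere
    and two homotopic inter-hemispheric pairs), every subject carrying
    every edge with five expected streamlines, 1 mm spatial jitter,
    distinct per-edge scalar values on a 0.2 background, no noise.
    """

    grid_dim: tuple[int, int, int] = (48, 48, 48)
    voxsize: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_regions_per_hemisphere: int = 2
    region_size: int = 8          # voxels, cuboid edge
    edges: list[PhantomEdge] | None = None
    jitter_sigma: float = 1.0     # mm
    background_scalar: float = 0.2
    noise_sd: float = 0.0
    n_streamline_points: int = 30
    n_loops_per_edge: int = 0     # injected >360-degree outliers
    n_outliers_per_edge: int = 0  # injected off-axis outliers
    outlier_offset: float = 30.0  # mm
    seed: int = 0

    def __post_init__(self):
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.edges is None:
            n = self.n_regions_per_hemisphere
            scalars = [0.4, 0.5, 0.6, 0.7, 0.45, 0.55, 0.65, 0.75]
            edges = []
            for h_base in (0, n):  # intra-hemispheric chains (low-z lane)
                for k in range(n - 1):
                    edges.append((h_base + k + 1, h_base + k + 2, -1))
            for k in range(n):     # homotopic inter-hemispheric pairs (high-z lane)
                edges.append((k + 1, n + k + 1, +1))
            off = max(min(3.0, self.region_size / 2.0 - 1.0), 0.0)
            self.edges = [
                PhantomEdge(i, j, scalar=scalars[e % len(scalars)],
                            apex_offset=6.0 * sign, anchor_offset=off * sign)
                for e, (i, j, sign) in enumerate(edges)
            ]

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = np.diag(self.voxsize)
        A[:3, 3] = -(np.asarray(self.grid_dim) - 1) * np.asarray(self.voxsize) / 2.0
        return A

    def subject_rng(self, subject: int, purpose: int = 0) -> np.random.Generator:
        """Documented seed-splitting rule: child stream (subject, purpose)."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(subject, purpose))
        )

    def ground_truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                code_i=[e.i for e in self.edges],
                code_j=[e.j for e in self.edges],
                presence_prob=[e.presence_prob for e in self.edges],
                rate=[e.rate for e in self.edges],
                scalar=[e.scalar for e in self.edges],
            )
        )


def make_phantom_parcellation(spec: PhantomSpec) -> LabelVolume:
    """Block parcellation: cuboid regions, hemisphere by x-midline rule.

    Left-hemisphere regions (codes 1..n) sit in the low-x half, their
    mirrored right-hemisphere counterparts (codes n+1..2n) in the
    high-x half; the unlabeled background acts as the white-matter
    corridor.  Raises if the requested regions do not fit the grid.
    """
    dim = np.asarray(spec.grid_dim)
    n = spec.n_regions_per_hemisphere
    if n < 1:
        raise ValueError("need at least one region per hemisphere")
    size = spec.region_size
    margin = 5
    if size + 2 * margin > dim[0] // 2 or size + 2 * margin > dim[2]:
        raise ValueError("regions do not fit the grid")
    if n == 1:
        y_slots = [(int(dim[1]) - size) // 2]
    else:
        span = int(dim[1]) - 2 * margin - size
        y_slots = [margin + round(k * span / (n - 1)) for k in range(n)]
        if any(b - a < size for a, b in zip(y_slots, y_slots[1:])):
            raise ValueError("regions do not fit the grid")
    labels = np.zeros(tuple(int(d) for d in dim), dtype=np.int32)
    x_left = margin
    x_right = int(dim[0]) - margin - size
    z0 = (int(dim[2]) - size) // 2
    rows = []
    affine = spec.affine
    for k in range(n):
        y0 = y_slots[k]
        for code, x0, hemi in ((k + 1, x_left, "L"), (n + k + 1, x_right, "R")):
            labels[x0:x0 + size, y0:y0 + size, z0:z0 + size] = code
            cvox = np.array([x0 + (size - 1) / 2, y0 + (size - 1) / 2,
                             z0 + (size - 1) / 2])
            cmm = affine[:3, :3] @ cvox + affine[:3, 3]
            rgb = _PALETTE[(code - 1) % len(_PALETTE)]
            rows.append(dict(code=code, name=f"{hemi}{k + 1}", hemisphere=hemi,
                             R=rgb[0], G=rgb[1], B=rgb[2],
                             x=cmm[0], y=cmm[1], z=cmm[2]))
    table = pd.DataFrame(sorted(rows, key=lambda r: r["code"]),
                         columns=LABEL_TABLE_COLUMNS)
    return LabelVolume(labels=labels, affine=affine, table=table)


def phantom_wm_mask(p: LabelVolume) -> np.ndarray:
    """The phantom's white-matter corridor: every unlabeled voxel."""
    return p.labels == 0


def _region_box_mm(p: LabelVolume, code: int) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-center bounds (mm) of a region's block: (lo, hi)."""
    vox = np.argwhere(p.labels == code)
    if vox.size == 0:
        raise ValueError(f"region {code} has no voxels")
    lo = p.affine[:3, :3] @ vox.min(axis=0) + p.affine[:3, 3]
    hi = p.affine[:3, :3] @ vox.max(axis=0) + p.affine[:3, 3]
    return np.minimum(lo, hi), np.maximum(lo, hi)


def _edge_anchors(p: LabelVolume, edge: PhantomEdge) -> tuple:
    """Mean-arc anchors of an edge plus the endpoint clipping boxes."""
    boxes = []
    anchors = []
    for code in (edge.i, edge.j):
        lo, hi = _region_box_mm(p, code)
        center = (lo + hi) / 2.0
        anchor = center + np.array([0.0, 0.0, edge.anchor_offset])
        anchors.append(np.clip(anchor, lo, hi))
        boxes.append((lo, hi))
    return anchors[0], anchors[1], boxes[0], boxes[1]


def _perpendicular(u: np.ndarray) -> np.ndarray:
    """Unit vector perpendicular to u, biased toward +z."""
    z = np.array([0.0, 0.0, 1.0])
    w = z - (z @ u) * u
    if np.linalg.norm(w) < 1e-6:
        w = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ u) * u
    return w / np.linalg.norm(w)


def _quadratic_arc(p0, apex, p1, n_points: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * t * (1 - t) * apex + (t ** 2) * p1


def _edge_streamlines(
    p: LabelVolume, spec: PhantomSpec, edge: PhantomEdge, rng: np.random.Generator
) -> list[np.ndarray]:
    """All streamlines of one edge for one subject (may be empty)."""
    if rng.random() >= edge.presence_prob:
        return []
    count = max(int(rng.poisson(edge.rate)), 1)
    a, b, box_a, box_b = _edge_anchors(p, edge)
    u = (b - a) / np.linalg.norm(b - a)
    perp = _perpendicular(u)
    sigma = spec.jitter_sigma
    out = []
    for _ in range(count):
        e0, e1 = a.copy(), b.copy()
        if sigma > 0:
            # endpoint jitter clipped into the region block
            e0 = np.clip(a + rng.normal(0.0, sigma, 3), *box_a)
            e1 = np.clip(b + rng.normal(0.0, sigma, 3), *box_b)
        apex = (e0 + e1) / 2.0 + perp * edge.apex_offset
        if sigma > 0:
            apex = apex + rng.normal(0.0, sigma, 3)
        out.append(_quadratic_arc(e0, apex, e1, spec.n_streamline_points))
    for _ in range(spec.n_loops_per_edge):
        out.append(_loop_streamline(a, b, u, perp, spec))
    for _ in range(spec.n_outliers_per_edge):
        apex = (a + b) / 2.0 + perp * spec.outlier_offset
        out.append(_quadratic_arc(a, apex, b, spec.n_streamline_points))
    return out


def _loop_streamline(a, b, u, perp, spec: PhantomSpec) -> np.ndarray:
    """A streamline from a to b performing 1.5 full turns (winding 540)."""
    n = max(spec.n_streamline_points, 60)
    t = np.linspace(0.0, 1.0, n)
    w = np.cross(u, perp)
    radius = 4.0
    theta = 2 * np.pi * 1.5 * t
    axis = a + np.outer(t, b - a)
    envelope = np.sin(np.pi * t) * radius  # pinched at the endpoints
    return axis + np.outer(envelope * np.cos(theta), perp) + np.outer(
        envelope * np.sin(theta), w
    )


def simulate_subject_tractogram(
    p: LabelVolume, spec: PhantomSpec, subject: int
) -> Tractogram:
    """One subject's tractogram from the ground-truth edge list.

    Each edge is present with its ``presence_prob``; present edges
    contribute ``max(Poisson(rate), 1)`` jittered arcs whose endpoints
    lie inside the two region blocks and whose lengths fall inside the
    20-200 mm dissection band by construction.
    """
    rng = spec.subject_rng(subject, purpose=0)
    streamlines: list[np.ndarray] = []
    for edge in spec.edges:
        streamlines.extend(_edge_streamlines(p, spec, edge, rng))
    return Tractogram(streamlines, spec.affine, spec.grid_dim, spec.voxsize)


def make_scalar_map(
    p: LabelVolume, spec: PhantomSpec, subject: int
) -> ScalarVolume:
    """The subject's scalar volume with known per-edge values.

    Background ``b`` everywhere; the voxels traversed by each edge the
    subject carries (presence redrawn from the same seed stream as the
    tractogram, so the two are consistent) are set to the edge's scalar
    value, later-listed edges overwriting earlier ones.  "Traversed"
    means within the edge's jitter envelope: a tube of radius
    ``1 + 2.5 sigma`` mm around the mean arc, slightly extended past the
    anchors, so that every voxel any plausible realisation of the bundle
    can reach carries the edge value.  Gaussian noise of sd ``noise_sd``
    is added from an independent random stream when requested.
    """
    rng = spec.subject_rng(subject, purpose=0)
    values = np.full(spec.grid_dim, spec.background_scalar, dtype=float)
    for edge in spec.edges:
        streams = _edge_streamlines(p, spec, edge, rng)
        if not streams:
            continue
        values[_edge_tube_mask(p, spec, edge)] = edge.scalar
    if spec.noise_sd > 0:
        noise_rng = spec.subject_rng(subject, purpose=1)
        values = values + noise_rng.normal(0.0, spec.noise_sd, values.shape)
    return ScalarVolume(values=values, affine=spec.affine, modality="phantom")


def _edge_tube_mask(p: LabelVolume, spec: PhantomSpec, edge: PhantomEdge) -> np.ndarray:
    """Voxels within the edge's jitter envelope around its mean arc."""
    from scipy.spatial import cKDTree

    radius = 1.0 + 2.5 * spec.jitter_sigma
    a, b, _, _ = _edge_anchors(p, edge)
    u = (b - a) / np.linalg.norm(b - a)
    ext = 2.0  # mm past the anchors, covering endpoint jitter
    apex = (a + b) / 2.0 + _perpendicular(u) * edge.apex_offset
    arc = _quadratic_arc(a - u * ext, apex, b + u * ext,
                         max(4 * spec.n_streamline_points, 120))
    tree = cKDTree(arc)
    shape = np.asarray(spec.grid_dim)
    idx = np.indices(tuple(shape)).reshape(3, -1).T.astype(float)
    mm = idx @ spec.affine[:3, :3].T + spec.affine[:3, 3]
    dist, _ = tree.query(mm, k=1)
    return (dist <= radius).reshape(tuple(shape))


def make_lesion_mask(p: LabelVolume, center_mm, radius_mm: float) -> np.ndarray:
    """Spherical binary lesion: voxels whose center lies within the radius.

    A center outside the grid yields an empty mask with a warning; a
    radius smaller than half a voxel may select no voxel at all.
    """
    import logging

    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    center = np.asarray(center_mm, dtype=float)
    shape = np.asarray(p.labels.shape)
    inv = np.linalg.inv(p.affine)
    cvox = inv[:3, :3] @ center + inv[:3, 3]
    if np.any(cvox < -0.5) or np.any(cvox > shape - 0.5):
        logging.getLogger(__name__).warning(
            "lesion center %s lies outside the grid; empty mask", center
        )
        return np.zeros(tuple(shape), dtype=bool)
    idx = np.indices(tuple(shape)).reshape(3, -1).T.astype(float)
    mm = idx @ p.affine[:3, :3].T + p.affine[:3, 3]
    dist = np.linalg.norm(mm - center, axis=1)
    return (dist <= radius_mm).reshape(tuple(shape))


@dataclass
class PhantomDataset:
    """A fully realised phantom cohort with its ground truth."""

    spec: PhantomSpec
    parcellation: LabelVolume
    tractograms: list[Tractogram]
    scalars: list[ScalarVolume]
    ground_truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def make_phantom_dataset(
    spec: PhantomSpec, n_subjects: int, with_scalars: bool = True
) -> PhantomDataset:
    """Generate parcellation + per-subject tractograms (and scalar maps)."""
    p = make_phantom_parcellation(spec)
    tracts = [simulate_subject_tractogram(p, spec, s) for s in range(n_subjects)]
    scalars = (
        [make_scalar_map(p, spec, s) for s in range(n_subjects)]
        if with_scalars else []
    )
    return PhantomDataset(
        spec=spec, parcellation=p, tractograms=tracts, scalars=scalars,
        ground_truth=spec.ground_truth_frame(),
    )
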