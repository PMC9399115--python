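"""Atlas application to user volumes.

An atlas carries, per retained connection, a sparse voxel map with the
fraction of subjects whose bundle traverses each voxel.  Applying it to
a scalar volume (e.g. an FA map pre-warped to the atlas grid) yields a
connection-weighted matrix without any tractography: per connection, the
mean/median/std of the scalar over the bundle's thresholded voxels.  The
two free parameters are the voxel-wise probability threshold ``p_thr``
and the inter-subject consistency threshold ``c_thr`` (recommended
application setting: both 0.3).

Binary masks query which bundles a lesion or ROI touches; a lesion
report quantifies per-connection lesion load (probability-weighted
fraction of the bundle inside the lesion) — the "dysconnectome" of a
focal lesion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AtlasModel, connectivity_density
from .dissect import LabelVolume

logger = logging.getLogger(__name__)


@dataclass
class ScalarVolume:
    """A scalar map on the atlas grid (e.g. FA in template space)."""

    values: np.ndarray
    affine: np.ndarray
    modality: str = "scalar"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("scalar volume must be 3-D")
        self.affine = np.asarray(self.affine, dtype=float)


def _check_grid(a: AtlasModel, shape, affine) -> None:
    if tuple(shape) != tuple(a.header.dim):
        raise ValueError(
            f"volume grid {tuple(shape)} does not match atlas grid {a.header.dim} "
            "(no silent resampling; warp inputs to the atlas grid first)"
        )
    if affine is not None and not np.allclose(affine, a.header.affine, atol=1e-6):
        raise ValueError("volume affine does not match the atlas affine")


@dataclass
class ScalarConnectome:
    """Scalar-weighted connectivity matrices with an explicit valid mask.

    Invalid entries (connection below the consistency threshold, or an
    empty thresholded voxel set) are flagged rather than set to zero,
    since 0 is a legal scalar mean.
    """

    codes: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    std: np.ndarray
    valid: np.ndarray
    scale: int = 1
    p_thr: float = 0.0
    c_thr: float = 0.0

    def __post_init__(self):
        n = len(self.codes)
        for name in ("mean", "median", "std", "valid"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of valid connections."""
        rows = []
        n = len(self.codes)
        for i in range(n):
            for j in range(i + 1, n):
                if self.valid[i, j]:
                    rows.append(
                        dict(code_i=int(self.codes[i]), code_j=int(self.codes[j]),
                             mean=self.mean[i, j], median=self.median[i, j],
                             std=self.std[i, j])
                    )
        return pd.DataFrame(rows, columns=["code_i", "code_j", "mean", "median", "std"])


@dataclass
class LesionReport:
    """Per-connection lesion load and per-region aggregates."""

    pairs: list[tuple[int, int]]
    load: np.ndarray            # probability-weighted fraction in [0, 1]
    voxel_fraction: np.ndarray  # unweighted voxel fraction in [0, 1]
    affected: np.ndarray        # load > 0
    region_load: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                code_i=[p[0] for p in self.pairs],
                code_j=[p[1] for p in self.pairs],
                load=self.load,
                voxel_fraction=self.voxel_fraction,
                affected=self.affected,
            )
        )


def bundle_voxel_set(a: AtlasModel, pair: tuple[int, int], p_thr: float = 0.0) -> np.ndarray:
    """Voxel indices of a bundle at probability >= ``p_thr`` (inclusive)."""
    pair = (min(pair), max(pair))
    if pair not in a.spams:
        near = sorted(a.spams)[:5]
        raise KeyError(f"bundle {pair} not in atlas; available pairs include {near}")
    if not 0.0 <= p_thr <= 1.0:
        raise ValueError("p_thr must lie in [0, 1]")
    spam = a.spams[pair]
    return spam.voxels[spam.probabilities >= p_thr]


def _valid_pairs(a: AtlasModel, c_thr: float) -> list[tuple[int, int]]:
    """Retained pairs meeting the consistency threshold (fraction of S)."""
    S = a.nsubjects
    min_subjects = math.ceil(c_thr * S)
    out = []
    for pair in a.pairs:
        i = a.matrices.index_of(pair[0])
        j = a.matrices.index_of(pair[1])
        if a.matrices.consistency[i, j] >= min_subjects:
            out.append(pair)
    return out


def scalar_connectome(
    a: AtlasModel,
    v: ScalarVolume,
    p_thr: float = 0.3,
    c_thr: float = 0.30,
    scale: int = 1,
) -> ScalarConnectome:
    """Scalar-weighted connectivity matrices from an atlas and a volume.

    For every retained pair whose consistency fraction is >= ``c_thr``
    and whose thresholded voxel set is non-empty, computes the mean,
    median and population standard deviation of the volume over those
    voxels.  Other entries are flagged invalid.
    """
    _check_grid(a, v.values.shape, v.affine)
    if not 0.0 <= c_thr <= 1.0:
        raise ValueError("c_thr must lie in [0, 1]")
    codes = a.matrices.codes
    n = len(codes)
    mean = np.zeros((n, n))
    median = np.zeros((n, n))
    std = np.zeros((n, n))
    valid = np.zeros((n, n), dtype=bool)
    for pair in _valid_pairs(a, c_thr):
        vox = bundle_voxel_set(a, pair, p_thr)
        if vox.shape[0] == 0:
            continue
        vals = v.values[vox[:, 0], vox[:, 1], vox[:, 2]]
        i = a.matrices.index_of(pair[0])
        j = a.matrices.index_of(pair[1])
        mean[i, j] = mean[j, i] = float(vals.mean())
        median[i, j] = median[j, i] = float(np.median(vals))
        std[i, j] = std[j, i] = float(vals.std())  # population (1/n)
        valid[i, j] = valid[j, i] = True
    return ScalarConnectome(
        codes=codes, mean=mean, median=median, std=std, valid=valid,
        scale=scale, p_thr=p_thr, c_thr=c_thr,
    )


def bundles_intersecting_mask(
    a: AtlasModel, mask: np.ndarray, p_thr: float = 0.0
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Bundles whose thresholded support meets a binary mask.

    Returns the intersecting pairs and the union of their thresholded
    supports as a binary volume.
    """
    mask = np.asarray(mask).astype(bool)
    _check_grid(a, mask.shape, None)
    hits: list[tuple[int, int]] = []
    union = np.zeros(a.header.dim, dtype=bool)
    for pair in a.pairs:
        vox = bundle_voxel_set(a, pair, p_thr)
        if vox.shape[0] == 0:
            continue
        inside = mask[vox[:, 0], vox[:, 1], vox[:, 2]]
        if inside.any():
            hits.append(pair)
            union[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return hits, union


def bundles_connecting_rois(
    a: AtlasModel, rois: LabelVolume | np.ndarray, p_thr: float = 0.0
) -> list[tuple[int, int]]:
    """Bundles whose thresholded support touches two or more distinct ROIs."""
    labels = rois.labels if isinstance(rois, LabelVolume) else np.asarray(rois)
    _check_grid(a, labels.shape, None)
    present = np.unique(labels)
    present = present[present != 0]
    if present.size < 2:
        logger.info("bundles_connecting_rois: fewer than two ROI labels; empty result")
        return []
    out = []
    for pair in a.pairs:
        vox = bundle_voxel_set(a, pair, p_thr)
        if vox.shape[0] == 0:
            continue
        touched = np.unique(labels[vox[:, 0], vox[:, 1], vox[:, 2]])
        if (touched != 0).sum() >= 2:
            out.append(pair)
    return out


def lesion_impact(
    a: AtlasModel,
    lesion: np.ndarray,
    p_thr: float = 0.0,
    c_thr: float = 0.0,
    scalar: ScalarVolume | None = None,
) -> tuple[LesionReport, pd.DataFrame | None]:
    """Per-connection lesion load of a focal lesion mask.

    For each valid pair: load = sum of voxel probabilities over
    support-inside-lesion divided by the sum over the whole thresholded
    support (probability-weighted); ``voxel_fraction`` is the analogous
    unweighted ratio.  ``affected`` flags load > 0.  Per-region
    aggregate sums the loads of incident pairs.  If a scalar volume is
    given, a per-bundle mean/median/std table over the thresholded
    support is returned as well.
    """
    lesion = np.asarray(lesion).astype(bool)
    _check_grid(a, lesion.shape, None)
    pairs, loads, fracs = [], [], []
    scalar_rows = []
    for pair in _valid_pairs(a, c_thr):
        vox = bundle_voxel_set(a, pair, p_thr)
        if vox.shape[0] == 0:
            continue
        spam = a.spams[pair]
        sel = spam.probabilities >= p_thr
        prob = spam.probabilities[sel]
        inside = lesion[vox[:, 0], vox[:, 1], vox[:, 2]]
        load = float(prob[inside].sum() / prob.sum())
        frac = float(inside.mean())
        pairs.append(pair)
        loads.append(load)
        fracs.append(frac)
        if scalar is not None:
            vals = scalar.values[vox[:, 0], vox[:, 1], vox[:, 2]]
            scalar_rows.append(
                dict(code_i=pair[0], code_j=pair[1], mean=float(vals.mean()),
                     median=float(np.median(vals)), std=float(vals.std()))
            )
    loads_arr = np.asarray(loads, dtype=float)
    region_load: dict[int, float] = {}
    for (i, j), load in zip(pairs, loads_arr):
        region_load[i] = region_load.get(i, 0.0) + load
        region_load[j] = region_load.get(j, 0.0) + load
    report = LesionReport(
        pairs=pairs, load=loads_arr,
        voxel_fraction=np.asarray(fracs, dtype=float),
        affected=loads_arr > 0, region_load=region_load,
    )
    table = pd.DataFrame(scalar_rows) if scalar is not None else None
    return report, table


def atlas_density_summary(a: AtlasModel) -> dict:
    """Per-scale summary: region count, bundle count, density percent."""
    n_gm = len(a.header.gmcodes)
    return {
        "n_regions": n_gm,
        "n_bundles": a.n_bundles,
        "density_percent": connectivity_density(n_gm, a.n_bundles),
    }
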