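"""Atlas serialization: the HDF5 bundle-atlas layout and NIfTI exports.

The on-disk layout has three groups:

* ``header`` — nsubjects, dim, voxsize, affine, gmregions, gmcodes,
  gmcolors, gmcoords;
* ``matrices`` — consistency, numbStlines, length (N_GM x N_GM);
* ``atlas`` — one dataset per retained bundle, named ``{a}_{b}`` with
  the two region codes (lower code first), each an N x 4 integer matrix:
  voxel X, Y, Z indices plus the per-voxel subject-consistency count.

Voxel coordinates are written 0-based; the reader can auto-detect a
1-based file against the header grid dimensions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import h5py

from .atlas import SPAM, AtlasHeader, AtlasModel, GroupMatrices


class AtlasFormatError(ValueError):
    """Raised when an atlas file violates the expected HDF5 layout."""


def write_atlas_h5(a: AtlasModel, path) -> None:
    """Write an atlas to the three-group HDF5 layout."""
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        hdr = f.create_group("header")
        hdr.create_dataset("nsubjects", data=np.int64(a.header.nsubjects))
        hdr.create_dataset("dim", data=np.asarray(a.header.dim, dtype=np.int64))
        hdr.create_dataset("voxsize", data=np.asarray(a.header.voxsize, dtype=np.float64))
        hdr.create_dataset("affine", data=a.header.affine.astype(np.float64))
        hdr.create_dataset("gmregions", data=np.asarray(a.header.gmregions, dtype=object), dtype=str_dt)
        hdr.create_dataset("gmcodes", data=a.header.gmcodes.astype(np.int64))
        hdr.create_dataset("gmcolors", data=a.header.gmcolors.astype(np.int64))
        hdr.create_dataset("gmcoords", data=a.header.gmcoords.astype(np.float64))
        mat = f.create_group("matrices")
        mat.create_dataset("consistency", data=a.matrices.consistency.astype(np.int64))
        mat.create_dataset("numbStlines", data=a.matrices.numbStlines.astype(np.float64))
        mat.create_dataset("length", data=a.matrices.length.astype(np.float64))
        grp = f.create_group("atlas")
        for (i, j), spam in sorted(a.spams.items()):
            table = np.column_stack([spam.voxels, spam.counts]).astype(np.int64)
            grp.create_dataset(f"{i}_{j}", data=table)


def read_atlas_h5(path, index_base: int | str = "auto") -> AtlasModel:
    """Read an atlas file, validating the layout and invariants.

    ``index_base`` handles files whose voxel coordinates are written
    1-based: ``0`` (as written by :func:`write_atlas_h5`), ``1``, or
    ``"auto"`` to detect from the coordinate range against ``dim``.
    Any missing group/dataset or shape violation raises
    :class:`AtlasFormatError` naming the offending path; no partial
    model is returned.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise AtlasFormatError(f"{path}: not a readable HDF5 file ({e})") from e
    with f:
        for grp in ("header", "matrices", "atlas"):
            if grp not in f:
                raise AtlasFormatError(f"{path}: missing group '{grp}'")
        hdr = f["header"]
        for ds in ("nsubjects", "dim", "voxsize", "affine",
                   "gmregions", "gmcodes", "gmcolors", "gmcoords"):
            if ds not in hdr:
                raise AtlasFormatError(f"{path}: missing dataset 'header/{ds}'")
        nsubjects = int(np.asarray(hdr["nsubjects"])[()])
        dim = tuple(int(d) for d in np.asarray(hdr["dim"]))
        voxsize = tuple(float(v) for v in np.asarray(hdr["voxsize"]))
        affine = np.asarray(hdr["affine"], dtype=float)
        if affine.shape != (4, 4):
            raise AtlasFormatError(f"{path}: 'header/affine' must be 4x4")
        gmregions = [
            s.decode("utf-8") if isinstance(s, bytes) else str(s)
            for s in np.asarray(hdr["gmregions"])
        ]
        gmcodes = np.asarray(hdr["gmcodes"], dtype=np.int64)
        gmcolors = np.asarray(hdr["gmcolors"], dtype=np.int64)
        gmcoords = np.asarray(hdr["gmcoords"], dtype=float)
        n = len(gmregions)
        for name, arr, cols in (("gmcodes", gmcodes, None),
                                ("gmcolors", gmcolors, 3),
                                ("gmcoords", gmcoords, 3)):
            if arr.shape[0] != n or (cols and (arr.ndim != 2 or arr.shape[1] != cols)):
                raise AtlasFormatError(f"{path}: 'header/{name}' shape mismatch")

        mat = f["matrices"]
        mats = {}
        for ds in ("consistency", "numbStlines", "length"):
            if ds not in mat:
                raise AtlasFormatError(f"{path}: missing dataset 'matrices/{ds}'")
            m = np.asarray(mat[ds])
            if m.shape != (n, n):
                raise AtlasFormatError(f"{path}: 'matrices/{ds}' must be {n}x{n}")
            mats[ds] = m

        spams: dict[tuple[int, int], SPAM] = {}
        codes_set = set(int(c) for c in gmcodes)
        raw_tables = {}
        max_coord = -1
        for name in f["atlas"]:
            table = np.asarray(f["atlas"][name])
            if table.ndim != 2 or table.shape[1] != 4:
                raise AtlasFormatError(f"{path}: 'atlas/{name}' must be Nx4")
            try:
                i, j = (int(v) for v in name.split("_"))
            except ValueError:
                raise AtlasFormatError(
                    f"{path}: dataset name 'atlas/{name}' is not '<code>_<code>'"
                ) from None
            if i not in codes_set or j not in codes_set:
                raise AtlasFormatError(f"{path}: 'atlas/{name}' codes not in gmcodes")
            if table.size and table[:, 3].max() > nsubjects:
                raise AtlasFormatError(
                    f"{path}: 'atlas/{name}' consistency exceeds nsubjects (corrupt)"
                )
            raw_tables[(min(i, j), max(i, j))] = table
            if table.size:
                max_coord = max(max_coord, int(table[:, :3].max()))

        if index_base == "auto":
            base = 1 if max_coord >= max(dim) else 0
        else:
            base = int(index_base)
        for pair, table in raw_tables.items():
            vox = table[:, :3].astype(np.int64) - base
            if vox.size and (vox.min() < 0 or np.any(vox >= np.asarray(dim))):
                raise AtlasFormatError(
                    f"{path}: 'atlas/{pair[0]}_{pair[1]}' voxel indices out of grid"
                )
            spams[pair] = SPAM(
                pair=pair, voxels=vox, counts=table[:, 3], nsubjects=nsubjects
            )

    header = AtlasHeader(
        nsubjects=nsubjects, dim=dim, voxsize=voxsize, affine=affine,
        gmregions=gmregions, gmcodes=gmcodes, gmcolors=gmcolors, gmcoords=gmcoords,
    )
    matrices = GroupMatrices(
        codes=gmcodes, consistency=mats["consistency"],
        numbStlines=mats["numbStlines"], length=mats["length"],
        nsubjects=nsubjects,
    )
    return AtlasModel(header=header, matrices=matrices, spams=spams)


def export_bundle_probability_volume(
    a: AtlasModel, pair: tuple[int, int], p_thr: float = 0.0
) -> np.ndarray:
    """Dense probability volume of one bundle.

    Stored voxels with probability >= ``p_thr`` carry count/S; all other
    voxels are zero.
    """
    pair = (min(pair), max(pair))
    if pair not in a.spams:
        near = sorted(a.spams)[:5]
        raise KeyError(f"bundle {pair} not in atlas; available pairs include {near}")
    if not 0.0 <= p_thr <= 1.0:
        raise ValueError("p_thr must lie in [0, 1]")
    spam = a.spams[pair]
    vol = np.zeros(a.header.dim, dtype=float)
    prob = spam.probabilities
    sel = prob >= p_thr
    v = spam.voxels[sel]
    vol[v[:, 0], v[:, 1], v[:, 2]] = prob[sel]
    return vol


def export_color_coded_volume(a: AtlasModel, p_thr: float = 0.0) -> np.ndarray:
    """Color-coded bundle volume: (X, Y, Z, 3) float RGB.

    Each bundle's color is the mean of its two endpoint-region colors;
    each voxel's color is the probability-weighted average of the colors
    of the bundles traversing it.  Voxels with no bundle stay 0.
    """
    code_color = {
        int(c): a.header.gmcolors[k].astype(float)
        for k, c in enumerate(a.header.gmcodes)
    }
    accum = np.zeros(a.header.dim + (3,), dtype=float)
    weight = np.zeros(a.header.dim, dtype=float)
    for (i, j), spam in a.spams.items():
        color = (code_color[i] + code_color[j]) / 2.0
        prob = spam.probabilities
        sel = prob >= p_thr
        v = spam.voxels[sel]
        p = prob[sel]
        np.add.at(accum, (v[:, 0], v[:, 1], v[:, 2]), p[:, None] * color)
        np.add.at(weight, (v[:, 0], v[:, 1], v[:, 2]), p)
    out = np.zeros_like(accum)
    nz = weight > 0
    out[nz] = accum[nz] / weight[nz, None]
    return out


def save_nifti(volume: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a volume as NIfTI-1 carrying the given affine."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(volume), np.asarray(affine, dtype=float)), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data array, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.affine)


def export_matrices_csv(a: AtlasModel, prefix) -> list[str]:
    """Write the three group matrices as CSV with region-code headers."""
    paths = []
    codes = a.matrices.codes
    for name in ("consistency", "numbStlines", "length"):
        m = getattr(a.matrices, name)
        path = f"{prefix}_{name}.csv"
        pd.DataFrame(m, index=codes, columns=codes).to_csv(path)
        paths.append(path)
    return paths
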