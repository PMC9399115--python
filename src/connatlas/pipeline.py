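"""End-to-end atlas construction from per-subject tractograms.

Orchestrates the full chain: dissection of every subject's tractogram
into cleaned region-pair bundles, per-bundle tract density images,
SPAM aggregation across subjects, group matrices, consensus
thresholding of the bundle list, and assembly of the final atlas model.
"""

from __future__ import annotations

import logging

import numpy as np

from .atlas import (
    SPAM,
    AtlasHeader,
    AtlasModel,
    assemble_atlas,
    build_spam,
    compute_tdi,
    consensus_threshold,
    group_connectivity,
)
from .dissect import LabelVolume, extract_bundles
from .tract import Tractogram

logger = logging.getLogger(__name__)


def header_from_parcellation(p: LabelVolume, nsubjects: int,
                             dim, voxsize) -> AtlasHeader:
    """Atlas header with GM metadata taken from the label table
    (regions ordered by ascending code, matching the matrices)."""
    table = p.table.sort_values("code")
    return AtlasHeader(
        nsubjects=nsubjects,
        dim=dim,
        voxsize=voxsize,
        affine=p.affine,
        gmregions=table["name"].tolist(),
        gmcodes=table["code"].to_numpy(),
        gmcolors=table[["R", "G", "B"]].to_numpy(),
        gmcoords=table[["x", "y", "z"]].to_numpy(),
    )


def build_atlas_from_subjects(
    tractograms: list[Tractogram],
    parcellation: LabelVolume,
    *,
    scale_id: int = 1,
    min_len: float = 20.0,
    max_len: float = 200.0,
    clean: bool = True,
    tree_threshold: float = 0.2,
    c_min: float = 0.0,
    n_bins: int = 10,
) -> AtlasModel:
    """Build a bundle atlas from a cohort of tractograms.

    Each subject is dissected independently; SPAMs count, per voxel, the
    subjects whose cleaned bundle traverses it; the consensus threshold
    (minimum subject fraction ``c_min``, ``n_bins`` length bins per
    hemisphere class) fixes the retained bundle list.
    """
    if not tractograms:
        raise ValueError("need at least one subject tractogram")
    S = len(tractograms)
    dim = tractograms[0].grid_dim
    voxsize = tractograms[0].grid_voxsize
    affine = tractograms[0].affine

    connectomes = []
    tdis_per_pair: dict[tuple[int, int], list] = {}
    for s_idx, t in enumerate(tractograms):
        bundles, connectome = extract_bundles(
            t, parcellation, min_len, max_len,
            scale_id=scale_id, clean=clean, tree_threshold=tree_threshold,
        )
        connectomes.append(connectome)
        for pair, streams in bundles.pair_map.items():
            tdi = compute_tdi(streams, dim, affine, voxsize,
                              pair=pair, subject_id=s_idx)
            tdis_per_pair.setdefault(pair, []).append(tdi)
        logger.info("subject %d: %d bundles, %d streamlines kept",
                    s_idx, len(bundles.pair_map), bundles.n_streamlines())

    spams: dict[tuple[int, int], SPAM] = {}
    for pair, tdis in tdis_per_pair.items():
        spam, _ = build_spam(tdis, nsubjects=S)
        spams[pair] = spam

    group = group_connectivity(connectomes)
    hemis = {
        int(r["code"]): str(r["hemisphere"])
        for _, r in parcellation.table.iterrows()
    }
    retained = consensus_threshold(connectomes, group, hemis,
                                   c_min=c_min, n_bins=n_bins)
    retained &= set(spams)  # a retained pair must have an observed bundle
    header = header_from_parcellation(parcellation, S, dim, voxsize)
    return assemble_atlas(header, group, spams, retained)
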