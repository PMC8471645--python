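"""Segmentation post-processing: keep only the largest 3D connected component.

Deep-learning segmentations occasionally produce small spurious satellite
components; the cleanup rule retains, per zonal region, the connected
component with the most voxels (default 26-connectivity, i.e. voxels sharing
a face, edge, or corner are neighbours) and discards the rest.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .mask_io import BinaryMask, LabelVolume, NONPZ_LABEL, PZ_LABEL, Region, extract_region

__all__ = ["largest_component", "postprocess_label_volume"]

logger = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Return the largest connected component of a non-empty mask.

    Ties between equal-sized components are broken deterministically by
    keeping the component whose lexicographically smallest voxel index
    (slice, row, column) is smallest.  Idempotent; output is a subset of the
    input.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}, got {connectivity}")
    if mask.count == 0:
        raise ValueError("largest_component requires a non-empty mask")
    labels, n = ndimage.label(mask.voxels, structure=_STRUCTURES[connectivity])
    if n == 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if candidates.size > 1:
        # tie-break: earliest first occurrence in raster (slice,row,col) order
        uniq, first = np.unique(labels.ravel(), return_index=True)
        first_of = dict(zip(uniq.tolist(), first.tolist()))
        keep = min(candidates, key=lambda lab: first_of[lab])
    else:
        keep = candidates[0]
    return BinaryMask(labels == keep, mask.spacing, mask.origin, mask.region)


def postprocess_label_volume(lv: LabelVolume, connectivity: int = 26) -> LabelVolume:
    """Apply the largest-component rule to each zonal region independently.

    PZ and non-PZ are cleaned separately and recomposed; WP is re-derived
    downstream by merging, so a PZ satellite glued to non-PZ cannot survive
    through the merge.  An empty region is recorded with a warning, not an
    error.
    """
    out = np.zeros(lv.voxels.shape, dtype=np.int16)
    for region, label in ((Region.PZ, PZ_LABEL), (Region.NONPZ, NONPZ_LABEL)):
        mask = extract_region(lv, region)
        if mask.count == 0:
            logger.warning(
                "subject=%s scan=%s method=%s: region %s empty, nothing to post-process",
                lv.subject_id, lv.scan_id, lv.method_id, region.value,
            )
            continue
        cleaned = largest_component(mask, connectivity)
        if np.any(out[cleaned.voxels]):
            raise RuntimeError("post-processed regions overlap; input labels were not disjoint")
        out[cleaned.voxels] = label
    return LabelVolume(out, lv.spacing, lv.origin, lv.subject_id, lv.scan_id, lv.method_id)
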