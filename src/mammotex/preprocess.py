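"""Mask conditioning, grid harmonization and cohort exclusion filters.

Masks are smoothed by a morphological opening followed by a closing with a
3x3x3 cubic kernel, the standard cleanup for manually delineated lesions.
All channels are then resampled onto the reference grid (the DCE grid, on
which lesions are delineated); the tumor size is the mean of the axis-aligned
bounding-box extents in mm; tumors smaller than 5 mm (strictly) are excluded,
as are tumors missing any contrast, with an optional size-homogeneity window
(inclusive bounds).
"""

from __future__ import annotations

from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import CONTRASTS, DegenerateMaskError, SegmentationMask, Volume, VolumeSet

_CUBE3 = np.ones((3, 3, 3), dtype=bool)


def smooth_mask(mask: SegmentationMask) -> SegmentationMask:
    """Morphological open-then-close with a 3x3x3 cube; idempotent.

    Raises :class:`DegenerateMaskError` if the opening removes everything
    (e.g. an isolated voxel or a thread-like mask).
    """
    data = mask.data
    # pad so border voxels get the same treatment as interior ones
    padded = np.pad(data, 2)
    opened = ndimage.binary_opening(padded, structure=_CUBE3)
    if not opened.any():
        raise DegenerateMaskError("mask vanished under 3x3x3 opening")
    closed = ndimage.binary_closing(opened, structure=_CUBE3)
    out = closed[2:-2, 2:-2, 2:-2]
    if not out.any():
        raise DegenerateMaskError("mask vanished under smoothing")
    return SegmentationMask(out, mask.spacing)


def resample_to_reference(
    obj: Union[Volume, SegmentationMask],
    reference_shape: Tuple[int, int, int],
    reference_spacing: Tuple[float, float, float],
) -> Union[Volume, SegmentationMask]:
    """Resample a volume (trilinear) or mask (nearest-neighbor) onto a grid.

    Both grids are assumed to share their origin at voxel index 0 (channels
    are co-registered by acquisition); the physical position of index ``i``
    along an axis is ``i * spacing``.
    """
    is_mask = isinstance(obj, SegmentationMask)
    data = obj.data.astype(np.float64)
    if obj.shape == tuple(reference_shape) and obj.spacing == tuple(reference_spacing):
        return obj
    src_max_mm = [(n - 1) * s for n, s in zip(obj.shape, obj.spacing)]
    ref_max_mm = [(n - 1) * s for n, s in zip(reference_shape, reference_spacing)]
    if any(r > s + max(obj.spacing) * 1.5 + 1e-9 for r, s in zip(ref_max_mm, src_max_mm)):
        raise ValueError(
            "reference grid extends well beyond the source volume's physical extent"
        )
    coords = np.meshgrid(
        *[
            np.arange(n) * rs / ss
            for n, rs, ss in zip(reference_shape, reference_spacing, obj.spacing)
        ],
        indexing="ij",
    )
    order = 0 if is_mask else 1
    out = ndimage.map_coordinates(
        data, np.stack(coords), order=order, mode="nearest"
    )
    if is_mask:
        return SegmentationMask(out > 0.5, reference_spacing)
    return Volume(out, reference_spacing)


def harmonize_volume_set(vs: VolumeSet, mask: SegmentationMask) -> Tuple[VolumeSet, SegmentationMask]:
    """Bring all channels and the mask onto the DCE grid."""
    ref = vs["dce"]
    vols = {
        c: resample_to_reference(vs[c], ref.shape, ref.spacing) for c in vs.volumes
    }
    m = resample_to_reference(mask, ref.shape, ref.spacing)
    return VolumeSet(vols), m


def tumor_size_mm(mask: SegmentationMask) -> float:
    """Mean of the axis-aligned bounding-box extents, in mm.

    Extent along an axis = (number of voxel planes spanned) x spacing.
    """
    bbox = mask.bounding_box()
    extents = [(hi - lo + 1) * s for (lo, hi), s in zip(bbox, mask.spacing)]
    return float(np.mean(extents))


def apply_exclusions(
    cohort: pd.DataFrame,
    min_size_mm: float = 5.0,
    size_window: Optional[Tuple[float, float]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop tumors failing the inclusion rules; return (kept, exclusion log).

    Rules, applied in order per tumor:
      * any contrast path missing -> "missing contrast"
      * a truthy ``exclude`` flag column (manually curated, e.g. lesions
        spread through the whole gland) -> "manual exclusion"
      * ``size_mm < min_size_mm`` (strict) -> "size below minimum"
      * outside the inclusive ``size_window`` -> "outside size window"
    """
    reasons: List[dict] = []
    keep = np.ones(len(cohort), dtype=bool)
    for i, row in enumerate(cohort.itertuples(index=False)):
        r = row._asdict()
        reason = None
        if any(not str(r.get(f"{c}_path", "") or "").strip() for c in CONTRASTS):
            reason = "missing contrast"
        elif bool(r.get("exclude", False)):
            reason = "manual exclusion"
        elif float(r["size_mm"]) < min_size_mm:
            reason = "size below minimum"
        elif size_window is not None and not (
            size_window[0] <= float(r["size_mm"]) <= size_window[1]
        ):
            reason = "outside size window"
        if reason:
            keep[i] = False
            reasons.append({"tumor_id": r["tumor_id"], "reason": reason})
    log = pd.DataFrame(reasons, columns=["tumor_id", "reason"])
    kept = cohort.loc[keep].reset_index(drop=True)
    if kept.empty:
        import warnings

        warnings.warn("all tumors excluded", stacklevel=2)
    return kept, log
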