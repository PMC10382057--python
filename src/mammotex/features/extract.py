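"""Per-tumor feature extraction: one 342-value vector per contrast channel.

Quantization-dependent features (GLCM/GLRLM/GLSZM/NGTDM) are computed at six
gray-level counts (8, 16, 24, 32, 48, 64) and arithmetically averaged;
everything else is computed once.  The output is ordered exactly as the
feature inventory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from ..types import CONTRASTS, SegmentationMask, VolumeSet
from .frequency import frequency_features
from .inventory import FeatureConfig, FeatureInventory, build_inventory
from .matrices import compute_texture_matrices
from .quantize import quantize
from .shape_intensity import shape_intensity_features
from .texture import texture_features


def _crop_pair(volume: np.ndarray, mask: SegmentationMask, pad: int = 2):
    idx = np.nonzero(mask.data)
    lo = [max(0, int(i.min()) - pad) for i in idx]
    hi = [min(n, int(i.max()) + 1 + pad) for i, n in zip(idx, mask.data.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return volume[sl], SegmentationMask(mask.data[sl], mask.spacing)


def extract_features_single(
    volume: np.ndarray,
    mask: SegmentationMask,
    inventory: Optional[FeatureInventory] = None,
    config: FeatureConfig = FeatureConfig(),
) -> pd.Series:
    """Extract the full inventory for one volume/mask pair."""
    inventory = inventory or build_inventory(config)
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    vol_c, mask_c = _crop_pair(np.asarray(volume, dtype=np.float64), mask)

    values: Dict[str, float] = {}
    values.update(shape_intensity_features(vol_c, mask_c))
    values.update(frequency_features(vol_c, mask_c, config))

    acc: Dict[str, float] = {}
    for L in config.quantization_levels:
        q = quantize(vol_c, mask_c.data, L)
        mats = compute_texture_matrices(q, config.glcm_distances)
        for k, v in texture_features(mats).items():
            acc[k] = acc.get(k, 0.0) + v
    n_levels = len(config.quantization_levels)
    for k in acc:
        values[k] = acc[k] / n_levels

    out = pd.Series([values[n] for n in inventory.names], index=inventory.names)
    if not np.isfinite(out.to_numpy()).all():
        bad = out.index[~np.isfinite(out.to_numpy())].tolist()
        raise FloatingPointError(f"non-finite features: {bad[:5]}")
    return out


def extract_features(
    vs: VolumeSet,
    mask: SegmentationMask,
    inventory: Optional[FeatureInventory] = None,
    config: FeatureConfig = FeatureConfig(),
) -> Dict[str, pd.Series]:
    """Feature vector for each contrast channel of one tumor.

    Channels must already be harmonized onto a common grid matching the mask.
    """
    inventory = inventory or build_inventory(config)
    out: Dict[str, pd.Series] = {}
    for c in CONTRASTS:
        if c not in vs:
            raise KeyError(f"missing contrast channel: {c}")
        v = vs[c]
        if v.shape != mask.shape:
            raise ValueError(f"channel {c} not on the mask grid")
        out[c] = extract_features_single(v.data, mask, inventory, config)
    return out


def extract_cohort_features(
    cohort: pd.DataFrame,
    cohort_dir: Path,
    inventory: Optional[FeatureInventory] = None,
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Preprocess and extract every tumor in a cohort.

    Returns a long table with columns ``tumor_id, contrast, <feature...>``.
    Channels are harmonized onto the DCE grid and the mask is smoothed before
    extraction.
    """
    from ..preprocess import harmonize_volume_set, smooth_mask
    from ..types import load_mask, load_volume

    inventory = inventory or build_inventory(config)
    cohort_dir = Path(cohort_dir)
    rows = []
    for row in cohort.itertuples(index=False):
        vs = VolumeSet(
            {c: load_volume(cohort_dir / getattr(row, f"{c}_path")) for c in CONTRASTS}
        )
        mask = load_mask(cohort_dir / row.mask_path)
        mask = smooth_mask(mask)
        vs, mask = harmonize_volume_set(vs, mask)
        feats = extract_features(vs, mask, inventory, config)
        for c in CONTRASTS:
            rec = {"tumor_id": row.tumor_id, "contrast": c}
            rec.update(feats[c].to_dict())
            rows.append(rec)
    return pd.DataFrame(rows, columns=["tumor_id", "contrast"] + inventory.names)
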