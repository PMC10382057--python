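"""Gray-level quantization of in-mask intensities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class QuantizedVolume:
    """Integer-labeled volume: levels 1..L inside the mask, 0 outside.

    ``degenerate`` marks constant in-mask intensity (everything maps to
    level 1 and texture is meaningless).
    """

    labels: np.ndarray
    levels: int
    degenerate: bool

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def voxel_count(self) -> int:
        return int((self.labels > 0).sum())


def quantize(volume: np.ndarray, mask: np.ndarray, levels: int) -> QuantizedVolume:
    """Equal-width binning of the in-mask intensity range into ``levels`` bins.

    Bin index = floor(L * (v - min) / (max - min)) + 1, capped at L, so the
    in-mask minimum maps to level 1 and the maximum to level L.  Invariant to
    intensity shifts and positive rescaling by construction.
    """
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(volume, dtype=np.float64)
    lo = vals[mask].min()
    hi = vals[mask].max()
    labels = np.zeros(vals.shape, dtype=np.int32)
    if hi - lo <= 0:
        labels[mask] = 1
        return QuantizedVolume(labels, levels, degenerate=True)
    idx = np.floor(levels * (vals[mask] - lo) / (hi - lo)).astype(np.int32) + 1
    np.clip(idx, 1, levels, out=idx)
    labels[mask] = idx
    return QuantizedVolume(labels, levels, degenerate=False)
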