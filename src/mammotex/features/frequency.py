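"""Frequency-domain features: Gabor filter responses and radial-FFT summaries.

Gabor filters are applied slice-wise in the axial plane (MR voxels are
anisotropic through-plane), with kernels made DC-free so a constant image
gives zero response; each (frequency, orientation) pair is summarized by the
in-mask mean and SD of the complex-response magnitude.

The "other frequency" features come from the 3D power spectrum of the
mask-windowed crop: energy fractions and mean log-power in radial bands of
normalized frequency (cycles/voxel, bands on [0, 0.5]), plus global spectral
summaries (centroid, spread, entropy, flatness, roll-off, band fractions,
peak frequency).
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, Sequence

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

from ..types import SegmentationMask
from .inventory import FeatureConfig


def _crop(mask: np.ndarray, pad: int = 2):
    idx = np.nonzero(mask)
    lo = [max(0, int(i.min()) - pad) for i in idx]
    hi = [min(n, int(i.max()) + 1 + pad) for i, n in zip(idx, mask.shape)]
    return tuple(slice(a, b) for a, b in zip(lo, hi))


@lru_cache(maxsize=64)
def _dc_free_kernel(frequency: float, theta_deg: int) -> np.ndarray:
    """Complex Gabor kernel with zero DC gain and bounded spatial support.

    The envelope SD is capped at 4 px so low-frequency filters stay smaller
    than typical tumor crops; subtracting the kernel mean makes the response
    to a constant image exactly zero.  skimage's convention applies:
    theta = 0 modulates along the second (column) axis.
    """
    sigma = min(0.56 / frequency, 4.0)
    k = np.asarray(
        gabor_kernel(frequency, theta=np.deg2rad(theta_deg), sigma_x=sigma, sigma_y=sigma)
    )
    return k - k.mean()


def gabor_features(
    volume: np.ndarray,
    mask: SegmentationMask,
    frequencies: Sequence[float] = FeatureConfig().gabor_frequencies,
    orientations_deg: Sequence[int] = FeatureConfig().gabor_orientations_deg,
) -> Dict[str, float]:
    m = mask.data
    sl = _crop(m)
    vol = np.asarray(volume, dtype=np.float64)[sl]
    msk = m[sl]
    out: Dict[str, float] = {}
    for f in frequencies:
        for deg in orientations_deg:
            kern = _dc_free_kernel(float(f), int(deg))
            ph, pw = kern.shape[0] // 2, kern.shape[1] // 2
            # edge-replicated padding keeps the zero-DC property exact for
            # constant images and avoids wrap/zero-boundary artifacts
            vol_p = np.pad(vol, ((ph, ph), (pw, pw), (0, 0)), mode="edge")
            resp = fftconvolve(
                vol_p.astype(complex), kern[:, :, None], mode="same", axes=(0, 1)
            )[ph : ph + vol.shape[0], pw : pw + vol.shape[1], :]
            mag = np.abs(resp)[msk]
            out[f"gabor_f{f:g}_t{deg:03d}_mean"] = float(mag.mean())
            out[f"gabor_f{f:g}_t{deg:03d}_sd"] = float(mag.std())
    return out


def radial_fft_features(
    volume: np.ndarray, mask: SegmentationMask, n_bands: int = 16
) -> Dict[str, float]:
    m = mask.data
    sl = _crop(m)
    arr = np.where(m[sl], np.asarray(volume, dtype=np.float64)[sl], 0.0)
    power = np.abs(np.fft.fftn(arr)) ** 2
    freqs = np.meshgrid(*[np.fft.fftfreq(n) for n in arr.shape], indexing="ij")
    r = np.sqrt(sum(f**2 for f in freqs))
    band = np.minimum((r / 0.5 * n_bands).astype(int), n_bands - 1)

    total = power.sum()
    out: Dict[str, float] = {}
    band_e = np.zeros(n_bands)
    np.add.at(band_e, band.ravel(), power.ravel())
    band_n = np.bincount(band.ravel(), minlength=n_bands).astype(np.float64)
    frac = band_e / total if total > 0 else band_e
    for i in range(n_bands):
        out[f"freq_band_energy_{i:02d}"] = float(frac[i])
        mean_p = band_e[i] / band_n[i] if band_n[i] > 0 else 0.0
        out[f"freq_band_logpower_{i:02d}"] = float(np.log10(mean_p + 1e-12))

    if total > 0:
        pw = power / total
        centroid = float((pw * r).sum())
        spread = float(np.sqrt((pw * (r - centroid) ** 2).sum()))
        nzf = frac[frac > 0]
        s_entropy = float(-(nzf * np.log2(nzf)).sum())
        mean_bp = band_e.mean()
        geo = float(np.exp(np.log(band_e + 1e-12).mean()))
        flatness = geo / mean_bp if mean_bp > 0 else 0.0
        cum = np.cumsum(frac)
        roll_idx = int(np.searchsorted(cum, 0.85))
        rolloff = (roll_idx + 1) / n_bands * 0.5
        high = float(pw[r > 0.25].sum())
        low = float(pw[r < 0.10].sum())
        nz = r > 0
        peak = float(r.ravel()[np.argmax(np.where(nz, power, -np.inf).ravel())])
    else:
        centroid = spread = s_entropy = flatness = rolloff = high = low = peak = 0.0
    out.update(
        freq_spectral_centroid=centroid,
        freq_spectral_spread=spread,
        freq_spectral_entropy=s_entropy,
        freq_spectral_flatness=flatness,
        freq_rolloff_85=float(rolloff),
        freq_high_freq_fraction=high,
        freq_low_freq_fraction=low,
        freq_peak_freq=peak,
    )
    return out


def frequency_features(
    volume: np.ndarray,
    mask: SegmentationMask,
    config: FeatureConfig = FeatureConfig(),
) -> Dict[str, float]:
    out = gabor_features(
        volume, mask, config.gabor_frequencies, config.gabor_orientations_deg
    )
    out.update(radial_fft_features(volume, mask, config.n_freq_bands))
    return out
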