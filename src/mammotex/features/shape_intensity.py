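"""Quantization-independent features: shape, first-order intensity,
moments, wavelet-transform summaries and descriptor (LBP/gradient) features.

Shape features use physical units (mm) via the voxel spacing; the surface
area comes from a marching-cubes mesh.  3D geometric moments are computed on
the binary mask in physical coordinates and reported scale-invariantly
(eta_pqr = mu_pqr / V^(1+(p+q+r)/3)); J1..J3 are the rotation invariants of
the normalized second-moment tensor.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pywt
from scipy import stats
from skimage import measure
from skimage.feature import local_binary_pattern

from ..types import SegmentationMask


def _crop(mask: np.ndarray, pad: int = 1):
    idx = np.nonzero(mask)
    lo = [max(0, int(i.min()) - pad) for i in idx]
    hi = [min(n, int(i.max()) + 1 + pad) for i, n in zip(idx, mask.shape)]
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def _shape_features(mask: np.ndarray, spacing: Tuple[float, float, float]) -> Dict[str, float]:
    vox_vol = float(np.prod(spacing))
    n = int(mask.sum())
    volume = n * vox_vol

    sl = _crop(mask, pad=2)
    sub = np.pad(mask[sl].astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(sub, level=0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))

    r_eq = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphericity = (np.pi ** (1.0 / 3.0)) * (6.0 * volume) ** (2.0 / 3.0) / area
    f = {
        "volume_mm3": volume,
        "voxel_count": float(n),
        "surface_area_mm2": area,
        "sphericity": sphericity,
        "compactness1": volume / (np.sqrt(np.pi) * area ** 1.5),
        "compactness2": 36.0 * np.pi * volume**2 / area**3,
        "spherical_disproportion": area / (4.0 * np.pi * r_eq**2),
    }

    idx = np.nonzero(mask)
    ext = []
    for ax in range(3):
        ext.append((int(idx[ax].max()) - int(idx[ax].min()) + 1) * spacing[ax])
    f["bbox_extent_x_mm"], f["bbox_extent_y_mm"], f["bbox_extent_z_mm"] = ext
    f["bbox_volume_mm3"] = float(np.prod(ext))
    f["extent_fraction"] = volume / f["bbox_volume_mm3"]
    f["mean_size_mm"] = float(np.mean(ext))
    f["max_bbox_extent_mm"] = float(np.max(ext))

    coords = np.stack([idx[a] * spacing[a] for a in range(3)], axis=1).astype(np.float64)
    cov = np.cov(coords.T, bias=True) if n > 1 else np.zeros((3, 3))
    lam = np.sort(np.maximum(np.linalg.eigvalsh(cov), 0.0))[::-1]
    f["major_axis_mm"] = 4.0 * np.sqrt(lam[0])
    f["minor_axis_mm"] = 4.0 * np.sqrt(lam[1])
    f["least_axis_mm"] = 4.0 * np.sqrt(lam[2])
    if lam[0] > 1e-12:
        f["elongation"] = float(np.sqrt(lam[1] / lam[0]))
        f["flatness"] = float(np.sqrt(lam[2] / lam[0]))
    else:
        f["elongation"] = 1.0
        f["flatness"] = 1.0
    return f


def _intensity_features(vals: np.ndarray) -> Dict[str, float]:
    q = np.percentile(vals, [10, 25, 50, 75, 90])
    return {
        "intensity_mean": float(vals.mean()),
        "intensity_sd": float(vals.std()),
        "intensity_variance": float(vals.var()),
        "intensity_min": float(vals.min()),
        "intensity_max": float(vals.max()),
        "intensity_range": float(vals.max() - vals.min()),
        "intensity_median": float(q[2]),
        "intensity_p10": float(q[0]),
        "intensity_p25": float(q[1]),
        "intensity_p75": float(q[3]),
        "intensity_p90": float(q[4]),
    }


def _moment_features(
    vals: np.ndarray, mask: np.ndarray, spacing: Tuple[float, float, float]
) -> Dict[str, float]:
    sd = vals.std()
    f: Dict[str, float] = {
        "skewness": float(stats.skew(vals)) if sd > 1e-12 else 0.0,
        "kurtosis": float(stats.kurtosis(vals, fisher=False)) if sd > 1e-12 else 0.0,
        "energy": float((vals**2).sum()),
        "rms": float(np.sqrt((vals**2).mean())),
        "mean_abs_dev": float(np.abs(vals - vals.mean()).mean()),
        "cv": float(sd / abs(vals.mean())) if abs(vals.mean()) > 1e-12 else 0.0,
    }
    hist, _ = np.histogram(vals, bins=64)
    p = hist / hist.sum()
    nz = p > 0
    f["entropy"] = float(-(p[nz] * np.log2(p[nz])).sum())

    vox_vol = float(np.prod(spacing))
    idx = np.nonzero(mask)
    coords = np.stack([idx[a] * spacing[a] for a in range(3)], axis=1).astype(np.float64)
    c = coords - coords.mean(axis=0)
    V = mask.sum() * vox_vol  # mu_000 as an integral

    def mu(p_, q_, r_):
        return float((c[:, 0] ** p_ * c[:, 1] ** q_ * c[:, 2] ** r_).sum() * vox_vol)

    def eta(p_, q_, r_):
        order = p_ + q_ + r_
        return mu(p_, q_, r_) / V ** (1.0 + order / 3.0)

    for p_, q_, r_ in [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)]:
        f[f"eta_{p_}{q_}{r_}"] = eta(p_, q_, r_)
    for p_, q_, r_ in [(3, 0, 0), (0, 3, 0), (0, 0, 3), (1, 1, 1)]:
        f[f"eta_{p_}{q_}{r_}"] = eta(p_, q_, r_)
    M = np.array(
        [
            [eta(2, 0, 0), eta(1, 1, 0), eta(1, 0, 1)],
            [eta(1, 1, 0), eta(0, 2, 0), eta(0, 1, 1)],
            [eta(1, 0, 1), eta(0, 1, 1), eta(0, 0, 2)],
        ]
    )
    lam = np.linalg.eigvalsh(M)
    f["j1"] = float(lam.sum())
    f["j2"] = float(lam[0] * lam[1] + lam[0] * lam[2] + lam[1] * lam[2])
    f["j3"] = float(np.prod(lam))
    return f


def _wavelet_features(volume: np.ndarray, mask: np.ndarray) -> Dict[str, float]:
    sl = _crop(mask)
    arr = np.where(mask[sl], volume[sl], 0.0)
    coeffs = pywt.dwtn(arr, "db1")
    energies = {b: float((c**2).sum()) for b, c in coeffs.items()}
    total = sum(energies.values())
    f: Dict[str, float] = {}
    for band in ["aaa", "aad", "ada", "add", "daa", "dad", "dda", "ddd"]:
        c = coeffs[band].ravel()
        e = energies[band]
        f[f"{band}_energy_frac"] = e / total if total > 0 else 0.0
        p = c**2 / e if e > 0 else np.zeros_like(c)
        nz = p > 0
        f[f"{band}_entropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
        f[f"{band}_mean_abs"] = float(np.abs(c).mean())
    return f


def _descriptor_features(
    volume: np.ndarray, mask: np.ndarray, spacing: Tuple[float, float, float]
) -> Dict[str, float]:
    sl = _crop(mask)
    vol = volume[sl]
    msk = mask[sl]
    # LBP expects integer images: discretize to 256 gray levels first
    lo, hi = vol.min(), vol.max()
    vol_q = (
        np.round(255 * (vol - lo) / (hi - lo)).astype(np.uint8)
        if hi > lo
        else np.zeros(vol.shape, dtype=np.uint8)
    )
    # uniform LBP (P=8, R=1) on each through-plane slice, pooled in-mask
    codes = []
    for k in range(vol.shape[2]):
        if not msk[:, :, k].any() or vol.shape[0] < 3 or vol.shape[1] < 3:
            continue
        lbp = local_binary_pattern(vol_q[:, :, k], P=8, R=1, method="uniform")
        codes.append(lbp[msk[:, :, k]])
    f: Dict[str, float] = {}
    if codes:
        codes = np.concatenate(codes)
        hist = np.bincount(codes.astype(int), minlength=10)[:10].astype(np.float64)
        p = hist / hist.sum() if hist.sum() > 0 else hist
        for i in range(10):
            f[f"lbp_hist_{i:02d}"] = float(p[i])
        nz = p > 0
        f["lbp_entropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
        f["lbp_energy"] = float((p**2).sum())
        f["lbp_mean"] = float(codes.mean())
        f["lbp_var"] = float(codes.var())
    else:
        for i in range(10):
            f[f"lbp_hist_{i:02d}"] = 0.0
        f.update(lbp_entropy=0.0, lbp_energy=0.0, lbp_mean=0.0, lbp_var=0.0)
    if min(vol.shape) >= 2:
        grads = np.gradient(vol, *spacing)
        gmag = np.sqrt(sum(g**2 for g in grads))[msk]
        f["grad_mag_mean"] = float(gmag.mean())
        f["grad_mag_sd"] = float(gmag.std())
    else:
        f["grad_mag_mean"] = 0.0
        f["grad_mag_sd"] = 0.0
    return f


def shape_intensity_features(
    volume: np.ndarray, mask: SegmentationMask
) -> Dict[str, float]:
    """All quantization-independent non-frequency features, flat name map."""
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    vals = np.asarray(volume, dtype=np.float64)[m]
    out: Dict[str, float] = {}
    shape_f = _shape_features(m, mask.spacing)
    shape_f.update(_intensity_features(vals))
    for k, v in shape_f.items():
        out[f"conv_{k}"] = v
    for k, v in _moment_features(vals, m, mask.spacing).items():
        out[f"mom_{k}"] = v
    for k, v in _wavelet_features(np.asarray(volume, dtype=np.float64), m).items():
        out[f"wav_{k}"] = v
    for k, v in _descriptor_features(np.asarray(volume, dtype=np.float64), m, mask.spacing).items():
        out[f"desc_{k}"] = v
    return out
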