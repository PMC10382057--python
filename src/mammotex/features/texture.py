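"""Scalar texture features from gray-level matrices.

Formulas are the standard Haralick / Galloway–Chu / Thibault / Amadasun
definitions.  Entropies use log base 2 with the convention 0·log 0 = 0.
Degenerate inputs (constant regions, single-voxel masks, empty matrices)
map to documented finite limits — e.g. GLCM correlation of a zero-variance
region is 0, NGTDM busyness with a zero denominator is 0 — never NaN.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .inventory import GLRLM_BASE_FEATURES
from .matrices import TextureMatrixSet

_EPS = np.finfo(float).tiny


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _entropy(p: np.ndarray) -> float:
    return float(-_xlog2x(np.asarray(p, dtype=np.float64)).sum())


def glcm_features(P: np.ndarray) -> Dict[str, float]:
    """28 features of a normalized symmetric co-occurrence matrix."""
    L = P.shape[0]
    i = np.arange(1, L + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    total = P.sum()
    f: Dict[str, float] = {}
    if total <= 0:  # no voxel pairs at this distance
        return {name: 0.0 for name in _GLCM_NAMES}

    px = P.sum(axis=1)
    mu_x = float((i * px).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    # symmetric matrix: marginals coincide
    diff = np.abs(I - J)
    ssum = I + J

    # p_{x+y}(k), k = 2..2L ; p_{x-y}(k), k = 0..L-1
    p_sum = np.zeros(2 * L + 1)
    np.add.at(p_sum, ssum.ravel(), P.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, diff.ravel(), P.ravel())
    ks = np.arange(2 * L + 1)
    kd = np.arange(L)

    f["energy"] = float((P**2).sum())
    f["contrast"] = float(((I - J) ** 2 * P).sum())
    cov = float((I * J * P).sum()) - mu_x * mu_x
    f["correlation"] = cov / var_x if var_x > 1e-12 else 0.0
    f["variance"] = var_x
    f["inverse_difference_moment"] = float((P / (1.0 + (I - J) ** 2)).sum())
    f["sum_average"] = float((ks * p_sum).sum())
    f["sum_variance"] = float(((ks - f["sum_average"]) ** 2 * p_sum).sum())
    f["sum_entropy"] = _entropy(p_sum)
    ent = _entropy(P.ravel())
    f["entropy"] = ent
    f["difference_average"] = float((kd * p_diff).sum())
    f["difference_variance"] = float(
        ((kd - f["difference_average"]) ** 2 * p_diff).sum()
    )
    f["difference_entropy"] = _entropy(p_diff)

    hx = _entropy(px)
    pxy = np.outer(px, px)
    hxy1 = float(-(P * np.log2(pxy + _EPS)).sum())
    hxy2 = _entropy(pxy.ravel())
    f["imc1"] = (ent - hxy1) / hx if hx > 1e-12 else 0.0
    f["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent)))))
    f["autocorrelation"] = float((I * J * P).sum())
    cs = I + J - 2 * mu_x
    f["cluster_shade"] = float((cs**3 * P).sum())
    f["cluster_prominence"] = float((cs**4 * P).sum())
    f["cluster_tendency"] = float((cs**2 * P).sum())
    f["dissimilarity"] = float((diff * P).sum())
    f["inverse_difference"] = float((P / (1.0 + diff)).sum())
    f["inverse_difference_norm"] = float((P / (1.0 + diff / L)).sum())
    f["inverse_difference_moment_norm"] = float(
        (P / (1.0 + (diff / L) ** 2)).sum()
    )
    off = diff > 0
    f["inverse_variance"] = float((P[off] / diff[off] ** 2).sum()) if off.any() else 0.0
    f["max_probability"] = float(P.max())
    f["joint_average"] = mu_x
    f["third_difference_moment"] = float((diff**3 * P).sum())
    f["diagonal_probability"] = float(np.trace(P))
    denom = np.log2(L * L) if L > 1 else 1.0
    f["entropy_norm"] = ent / denom
    return f


_GLCM_NAMES = [
    "energy", "contrast", "correlation", "variance",
    "inverse_difference_moment", "sum_average", "sum_variance", "sum_entropy",
    "entropy", "difference_average", "difference_variance",
    "difference_entropy", "imc1", "imc2", "autocorrelation", "cluster_shade",
    "cluster_prominence", "cluster_tendency", "dissimilarity",
    "inverse_difference", "inverse_difference_norm",
    "inverse_difference_moment_norm", "inverse_variance", "max_probability",
    "joint_average", "third_difference_moment", "diagonal_probability",
    "entropy_norm",
]


def glrlm_features_single(R: np.ndarray, n_voxels: int) -> Dict[str, float]:
    """The 11 classical run-length features of one run-length matrix."""
    R = np.asarray(R, dtype=np.float64)
    L, Rm = R.shape
    Nr = R.sum()
    if Nr <= 0 or n_voxels <= 0:
        return {k: 0.0 for k in GLRLM_BASE_FEATURES}
    i = np.arange(1, L + 1)[:, None].astype(np.float64)
    r = np.arange(1, Rm + 1)[None, :].astype(np.float64)
    f = {
        "sre": float((R / r**2).sum() / Nr),
        "lre": float((R * r**2).sum() / Nr),
        "gln": float((R.sum(axis=1) ** 2).sum() / Nr),
        "rln": float((R.sum(axis=0) ** 2).sum() / Nr),
        "rp": float(Nr / n_voxels),
        "lgre": float((R / i**2).sum() / Nr),
        "hgre": float((R * i**2).sum() / Nr),
        "srlge": float((R / (i**2 * r**2)).sum() / Nr),
        "srhge": float((R * i**2 / r**2).sum() / Nr),
        "lrlge": float((R * r**2 / i**2).sum() / Nr),
        "lrhge": float((R * i**2 * r**2).sum() / Nr),
    }
    return f


def glrlm_features(per_dir: List[np.ndarray], merged: np.ndarray, n_voxels: int) -> Dict[str, float]:
    """Merged-matrix values plus directional mean/std/range per base feature.

    Run percentage of the merged matrix is normalized by voxels x directions
    so it stays in (0, 1].
    """
    n_dir = len(per_dir)
    out: Dict[str, float] = {}
    merged_f = glrlm_features_single(merged, n_voxels * n_dir)
    dir_f = [glrlm_features_single(m, n_voxels) for m in per_dir]
    for base in GLRLM_BASE_FEATURES:
        vals = np.array([d[base] for d in dir_f])
        out[f"{base}_merged"] = merged_f[base]
        out[f"{base}_dmean"] = float(vals.mean()) if vals.size else 0.0
        out[f"{base}_dstd"] = float(vals.std()) if vals.size else 0.0
        out[f"{base}_drange"] = float(vals.max() - vals.min()) if vals.size else 0.0
    return out


def glszm_features(Z: np.ndarray, n_voxels: int) -> Dict[str, float]:
    Z = np.asarray(Z, dtype=np.float64)
    L, Sm = Z.shape
    Nz = Z.sum()
    names = [
        "small_zone_emphasis", "large_zone_emphasis",
        "gray_level_nonuniformity", "gray_level_nonuniformity_norm",
        "zone_size_nonuniformity", "zone_size_nonuniformity_norm",
        "zone_percentage", "low_gray_zone_emphasis", "high_gray_zone_emphasis",
        "small_zone_low_gray_emphasis", "small_zone_high_gray_emphasis",
        "large_zone_low_gray_emphasis", "large_zone_high_gray_emphasis",
        "gray_level_variance", "zone_size_variance", "zone_entropy",
        "gray_level_mean", "zone_size_mean", "zone_size_max", "zone_count",
        "largest_zone_fraction", "zone_size_entropy", "gray_level_entropy",
        "zone_size_cv", "gray_level_cv", "zone_size_energy",
        "gray_level_energy", "joint_energy",
    ]
    if Nz <= 0 or n_voxels <= 0:
        return {k: 0.0 for k in names}
    i = np.arange(1, L + 1)[:, None].astype(np.float64)
    s = np.arange(1, Sm + 1)[None, :].astype(np.float64)
    p = Z / Nz
    pg = p.sum(axis=1)          # gray-level marginal
    ps = p.sum(axis=0)          # zone-size marginal
    iv = i.ravel()
    sv = s.ravel()
    gl_mean = float((iv * pg).sum())
    zs_mean = float((sv * ps).sum())
    gl_var = float(((iv - gl_mean) ** 2 * pg).sum())
    zs_var = float(((sv - zs_mean) ** 2 * ps).sum())
    nz_sizes = np.nonzero(Z.sum(axis=0))[0]
    zmax = float(nz_sizes[-1] + 1) if nz_sizes.size else 0.0
    f = {
        "small_zone_emphasis": float((Z / s**2).sum() / Nz),
        "large_zone_emphasis": float((Z * s**2).sum() / Nz),
        "gray_level_nonuniformity": float((Z.sum(axis=1) ** 2).sum() / Nz),
        "gray_level_nonuniformity_norm": float((Z.sum(axis=1) ** 2).sum() / Nz**2),
        "zone_size_nonuniformity": float((Z.sum(axis=0) ** 2).sum() / Nz),
        "zone_size_nonuniformity_norm": float((Z.sum(axis=0) ** 2).sum() / Nz**2),
        "zone_percentage": float(Nz / n_voxels),
        "low_gray_zone_emphasis": float((Z / i**2).sum() / Nz),
        "high_gray_zone_emphasis": float((Z * i**2).sum() / Nz),
        "small_zone_low_gray_emphasis": float((Z / (i**2 * s**2)).sum() / Nz),
        "small_zone_high_gray_emphasis": float((Z * i**2 / s**2).sum() / Nz),
        "large_zone_low_gray_emphasis": float((Z * s**2 / i**2).sum() / Nz),
        "large_zone_high_gray_emphasis": float((Z * i**2 * s**2).sum() / Nz),
        "gray_level_variance": gl_var,
        "zone_size_variance": zs_var,
        "zone_entropy": _entropy(p.ravel()),
        "gray_level_mean": gl_mean,
        "zone_size_mean": zs_mean,
        "zone_size_max": zmax,
        "zone_count": float(Nz),
        "largest_zone_fraction": zmax / n_voxels,
        "zone_size_entropy": _entropy(ps),
        "gray_level_entropy": _entropy(pg),
        "zone_size_cv": float(np.sqrt(zs_var) / zs_mean) if zs_mean > 0 else 0.0,
        "gray_level_cv": float(np.sqrt(gl_var) / gl_mean) if gl_mean > 0 else 0.0,
        "zone_size_energy": float((ps**2).sum()),
        "gray_level_energy": float((pg**2).sum()),
        "joint_energy": float((p**2).sum()),
    }
    return f


def ngtdm_features(s: np.ndarray, n: np.ndarray, levels: int) -> Dict[str, float]:
    s = np.asarray(s, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    names = [
        "coarseness", "contrast", "busyness", "complexity", "strength",
        "probability_entropy", "probability_uniformity", "s_sum", "s_mean",
        "s_max", "s_variance", "weighted_s_mean", "occupied_level_fraction",
        "tone_mean", "tone_variance", "tone_skewness",
    ]
    N = n.sum()
    if N <= 0:
        return {k: 0.0 for k in names}
    p = n / N
    occ = n > 0
    iv = np.arange(1, levels + 1, dtype=np.float64)
    ngp = int(occ.sum())

    ps_dot = float((p * s).sum())
    coarseness = 1.0 / ps_dot if ps_dot > 1e-12 else 1e6

    contrast = 0.0
    if ngp > 1:
        io = iv[occ]
        po = p[occ]
        dif2 = (io[:, None] - io[None, :]) ** 2
        contrast = float(
            (po[:, None] * po[None, :] * dif2).sum()
            / (ngp * (ngp - 1))
            * (s.sum() / N)
        )

    busy_den = 0.0
    if ngp > 1:
        io = iv[occ]
        po = p[occ]
        busy_den = float(np.abs(io[:, None] * po[:, None] - io[None, :] * po[None, :]).sum())
    busyness = ps_dot / busy_den if busy_den > 1e-12 else 0.0

    complexity = 0.0
    strength = 0.0
    if ngp > 1:
        io = iv[occ]
        po = p[occ]
        so = s[occ]
        absdif = np.abs(io[:, None] - io[None, :])
        num = (po[:, None] * so[:, None] + po[None, :] * so[None, :])
        den = po[:, None] + po[None, :]
        complexity = float((absdif * num / den).sum() / N)
        s_tot = s.sum()
        if s_tot > 1e-12:
            strength = float(((den) * (io[:, None] - io[None, :]) ** 2).sum() / s_tot)

    tone_mean = float((iv * p).sum())
    tone_var = float(((iv - tone_mean) ** 2 * p).sum())
    tone_sd = np.sqrt(tone_var)
    tone_skew = (
        float((((iv - tone_mean) / tone_sd) ** 3 * p).sum()) if tone_sd > 1e-12 else 0.0
    )
    so = s[occ]
    f = {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
        "probability_entropy": _entropy(p),
        "probability_uniformity": float((p**2).sum()),
        "s_sum": float(s.sum()),
        "s_mean": float(so.mean()) if so.size else 0.0,
        "s_max": float(s.max()),
        "s_variance": float(so.var()) if so.size else 0.0,
        "weighted_s_mean": ps_dot,
        "occupied_level_fraction": ngp / levels,
        "tone_mean": tone_mean,
        "tone_variance": tone_var,
        "tone_skewness": tone_skew,
    }
    return f


def texture_features(m: TextureMatrixSet) -> Dict[str, float]:
    """All matrix-based features of one quantized volume, flat name -> value."""
    out: Dict[str, float] = {}
    for d, P in m.glcm.items():
        for k, v in glcm_features(P).items():
            out[f"glcm_d{d}_{k}"] = v
    for k, v in glrlm_features(m.glrlm_directional, m.glrlm_merged, m.voxel_count).items():
        out[f"glrlm_{k}"] = v
    for k, v in glszm_features(m.glszm, m.voxel_count).items():
        out[f"glszm_{k}"] = v
    for k, v in ngtdm_features(m.ngtdm_s, m.ngtdm_n, m.levels).items():
        out[f"ngtdm_{k}"] = v
    return out
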