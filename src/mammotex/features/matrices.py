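"""Gray-level texture matrices: GLCM, GLRLM, GLSZM, NGTDM.

All matrices are computed in 3D over the in-mask voxels only:

* GLCM — co-occurrence counts over the 13 unique 3D direction offsets at a
  given voxel distance, summed over directions, symmetrized, and normalized
  to a probability matrix.
* GLRLM — run-length counts along the same 13 directions.  Per-direction
  matrices are kept (directional statistics are features) along with their
  merged sum.
* GLSZM — sizes of 26-connected constant-level zones (direction-free).
* NGTDM — per-level sums of |level − mean of 26-neighborhood|, neighbors
  restricted to the mask.

Everything is vectorized with array shifts; a brute-force per-voxel oracle
lives in the test suite and must agree exactly on small volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .quantize import QuantizedVolume

#: The 13 unique direction offsets of a 26-neighborhood (antipodal pairs
#: collapsed; first nonzero component positive).
DIRECTIONS_13: Tuple[Tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _shift(arr: np.ndarray, d: Sequence[int], fill) -> np.ndarray:
    """out[v] = arr[v + d], with `fill` where v + d leaves the array."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for n, di in zip(arr.shape, d):
        if di >= 0:
            dst.append(slice(0, n - di))
            src.append(slice(di, n))
        else:
            dst.append(slice(-di, n))
            src.append(slice(0, n + di))
    out[tuple(dst)] = arr[tuple(src)]
    return out


@dataclass
class TextureMatrixSet:
    """All four texture matrices for one quantized volume."""

    glcm: Dict[int, np.ndarray]            # distance -> L x L probabilities
    glrlm_directional: List[np.ndarray]    # 13 matrices, L x Rmax counts
    glrlm_merged: np.ndarray               # L x Rmax counts (sum over dirs)
    glszm: np.ndarray                      # L x Zmax zone counts
    ngtdm_s: np.ndarray                    # length-L sums of |i - nbhd mean|
    ngtdm_n: np.ndarray                    # length-L counted-voxel counts
    levels: int
    voxel_count: int
    degenerate: bool                       # single voxel or constant region


def glcm_matrix(q: QuantizedVolume, distance: int = 1) -> np.ndarray:
    """Direction-aggregated, symmetric, normalized co-occurrence matrix."""
    L = q.levels
    lab = q.labels
    counts = np.zeros(L * L, dtype=np.int64)
    for d in DIRECTIONS_13:
        off = tuple(distance * c for c in d)
        nb = _shift(lab, off, 0)
        valid = (lab > 0) & (nb > 0)
        if valid.any():
            code = (lab[valid].astype(np.int64) - 1) * L + (nb[valid] - 1)
            counts += np.bincount(code, minlength=L * L)
    C = counts.reshape(L, L).astype(np.float64)
    C = C + C.T
    total = C.sum()
    return C / total if total > 0 else C


def glrlm_matrices(q: QuantizedVolume) -> Tuple[List[np.ndarray], np.ndarray]:
    """Per-direction run-length matrices and their merged sum.

    Entry (i, r-1) counts maximal runs of level i+1 with length r along the
    direction (runs along d and −d are the same runs, counted once).
    """
    L = q.levels
    lab = q.labels
    valid = lab > 0
    max_run = max(lab.shape) * 2  # safe upper bound incl. diagonals
    per_dir: List[np.ndarray] = []
    for d in DIRECTIONS_13:
        cont = valid & _shift(valid, d, False) & (lab == _shift(lab, d, 0))
        back = tuple(-c for c in d)
        start = valid & ~_shift(cont, back, False)
        runlen = np.ones(lab.shape, dtype=np.int32)
        acc = cont.copy()
        k = 1
        while acc.any():
            runlen += acc
            off = tuple(k * c for c in d)
            acc &= _shift(cont, off, False)
            k += 1
            if k > max_run:  # pragma: no cover - safety net
                raise RuntimeError("run-length chase did not terminate")
        rows = lab[start] - 1
        cols = runlen[start] - 1
        rmax = int(cols.max()) + 1 if cols.size else 1
        mat = np.zeros((L, rmax), dtype=np.int64)
        np.add.at(mat, (rows, cols), 1)
        per_dir.append(mat)
    rmax = max(m.shape[1] for m in per_dir)
    merged = np.zeros((L, rmax), dtype=np.int64)
    for m in per_dir:
        merged[:, : m.shape[1]] += m
    return per_dir, merged


def glszm_matrix(q: QuantizedVolume) -> np.ndarray:
    """Zone-size matrix: entry (i, s-1) counts 26-connected zones of level
    i+1 with exactly s voxels."""
    L = q.levels
    lab = q.labels
    zones: List[Tuple[int, int]] = []
    for level in np.unique(lab[lab > 0]):
        comp, n = ndimage.label(lab == level, structure=_STRUCT_26)
        if n:
            sizes = np.bincount(comp.ravel())[1:]
            zones.extend((int(level), int(s)) for s in sizes)
    smax = max((s for _, s in zones), default=1)
    mat = np.zeros((L, smax), dtype=np.int64)
    for level, s in zones:
        mat[level - 1, s - 1] += 1
    return mat


def ngtdm_arrays(q: QuantizedVolume) -> Tuple[np.ndarray, np.ndarray]:
    """NGTDM sums s_i and voxel counts n_i per level.

    A voxel contributes if it has at least one in-mask 26-neighbor; the
    neighborhood mean uses in-mask neighbors only.
    """
    L = q.levels
    lab = q.labels.astype(np.float64)
    valid = q.labels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_count = ndimage.correlate(valid.astype(np.float64), kernel, mode="constant")
    nb_sum = ndimage.correlate(lab * valid, kernel, mode="constant")
    counted = valid & (nb_count > 0.5)
    diff = np.zeros_like(lab)
    diff[counted] = np.abs(lab[counted] - nb_sum[counted] / nb_count[counted])
    s = np.zeros(L)
    n = np.zeros(L, dtype=np.int64)
    lev = q.labels[counted] - 1
    np.add.at(s, lev, diff[counted])
    np.add.at(n, lev, 1)
    return s, n


def compute_texture_matrices(
    q: QuantizedVolume, glcm_distances: Sequence[int] = (1, 2, 3)
) -> TextureMatrixSet:
    per_dir, merged = glrlm_matrices(q)
    s, n = ngtdm_arrays(q)
    return TextureMatrixSet(
        glcm={d: glcm_matrix(q, d) for d in glcm_distances},
        glrlm_directional=per_dir,
        glrlm_merged=merged,
        glszm=glszm_matrix(q),
        ngtdm_s=s,
        ngtdm_n=n,
        levels=q.levels,
        voxel_count=q.voxel_count,
        degenerate=q.degenerate or q.voxel_count < 2,
    )
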