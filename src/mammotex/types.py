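"""Core in-memory containers shared across the pipeline.

A tumor is represented by three co-registered contrast channels (DCE,
Sub = DCE − T1 subtraction, T2) plus a binary segmentation mask.  Volumes
carry their voxel spacing in mm; all physical quantities downstream (sizes,
surface areas, moments) are computed in mm from these spacings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Tuple

import nibabel as nib
import numpy as np

#: Canonical contrast-channel names, in column order used everywhere.
CONTRASTS: Tuple[str, ...] = ("dce", "sub", "t2")

#: All mono/multi-contrast combinations evaluated, in report column order.
CONTRAST_COMBOS: Tuple[Tuple[str, ...], ...] = (
    ("dce",),
    ("sub",),
    ("t2",),
    ("dce", "sub"),
    ("dce", "t2"),
    ("sub", "t2"),
    ("dce", "sub", "t2"),
)


def combo_name(combo: Iterable[str]) -> str:
    return "+".join(c.upper() for c in combo)


class DegenerateMaskError(ValueError):
    """Raised when a mask is empty or destroyed by morphological cleaning."""


@dataclass
class Volume:
    """A 3D intensity array with isotropic-or-not voxel spacing in mm."""

    data: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class SegmentationMask:
    """Binary tumor mask on a voxel grid, spacing in mm."""

    data: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def bounding_box(self) -> Tuple[Tuple[int, int], ...]:
        """Inclusive (lo, hi) index bounds of nonzero voxels per axis."""
        if not self.data.any():
            raise DegenerateMaskError("mask is empty")
        out = []
        for ax in range(3):
            proj = np.any(self.data, axis=tuple(a for a in range(3) if a != ax))
            idx = np.nonzero(proj)[0]
            out.append((int(idx[0]), int(idx[-1])))
        return tuple(out)


@dataclass
class VolumeSet:
    """The three contrast channels for one tumor (possibly on differing grids
    before preprocessing; identical grids afterwards)."""

    volumes: Dict[str, Volume] = field(default_factory=dict)

    def __getitem__(self, contrast: str) -> Volume:
        return self.volumes[contrast]

    def __contains__(self, contrast: str) -> bool:
        return contrast in self.volumes

    @property
    def aligned(self) -> bool:
        vols = list(self.volumes.values())
        return all(
            v.shape == vols[0].shape and v.spacing == vols[0].spacing for v in vols
        )


# ---------------------------------------------------------------------------
# NIfTI I/O.  Spacing is carried in the affine diagonal; orientation handling
# is deliberately minimal because phantoms are generated in a fixed frame.
# ---------------------------------------------------------------------------


def save_nifti(data: np.ndarray, spacing: Tuple[float, float, float], path: Path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def load_volume(path: Path) -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asanyarray(img.dataobj, dtype=np.float64), spacing)


def load_mask(path: Path) -> SegmentationMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SegmentationMask(np.asanyarray(img.dataobj) > 0.5, spacing)
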