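"""Synthetic phantom cohorts emulating a multi-contrast breast-MRI study.

Real patient volumes for this kind of analysis are rarely shareable, so the
whole pipeline is exercised on seeded phantoms: perturbed-ellipsoid tumors
embedded in noisy background, with a spatially correlated intensity texture
inside the tumor whose parameters can be linked to class labels (ER/PR/HER2
status and IDC-vs-ILC histotype).  The cohort generator reproduces the
study-level statistics the analysis depends on: a right-skewed (log-normal)
tumor-size law with mean ~24.6 mm, SD ~16.6 mm and median ~20.3 mm, multiple
tumors per patient at a rate giving ~429 tumors from 323 patients, class
imbalance, and a configurable fraction of missing label cells.

Three channels are produced per tumor: DCE (contrast-enhanced T1, on the
reference grid), Sub = clip(DCE − T1, 0) where the T1 baseline is synthesized
with only a small tumor elevation, and T2 (generated on a coarser
through-plane grid to exercise resampling).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import sph_harm_y

from .types import CONTRASTS, SegmentationMask, Volume, VolumeSet, save_nifti

#: Binary classification tasks: column name -> (negative value, positive value).
TASKS: Dict[str, Tuple[str, str]] = {
    "er": ("-", "+"),
    "pr": ("-", "+"),
    "her2": ("-", "+"),
    "histotype": ("IDC", "ILC"),
}

COHORT_CSV_COLUMNS = [
    "tumor_id",
    "patient_id",
    "er",
    "pr",
    "her2",
    "histotype",
    "size_mm",
    "dce_path",
    "sub_path",
    "t2_path",
    "mask_path",
]


class PhantomSizingError(ValueError):
    """Tumor does not fit in the requested grid with the safety margin."""


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters for one phantom tumor.

    Intensity units are arbitrary; levels are chosen so that the DCE tumor is
    clearly hyperintense relative to background, as enhancing lesions are.
    ``texture_granularity_mm`` is the correlation length of the Gaussian
    random field painted inside the tumor; ``texture_amplitude`` its standard
    deviation per channel.
    """

    grid_shape: Tuple[int, int, int] = (48, 48, 32)
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 2.0)
    tumor_size_mm: float = 20.0
    shape_irregularity: float = 0.3
    background_level: Dict[str, float] = field(
        default_factory=lambda: {"dce": 100.0, "t1": 95.0, "t2": 120.0}
    )
    tumor_level: Dict[str, float] = field(
        default_factory=lambda: {"dce": 200.0, "t1": 110.0, "t2": 170.0}
    )
    noise_sd: Dict[str, float] = field(
        default_factory=lambda: {"dce": 6.0, "t1": 6.0, "t2": 8.0}
    )
    texture_amplitude: Dict[str, float] = field(
        default_factory=lambda: {"dce": 25.0, "t1": 5.0, "t2": 20.0}
    )
    texture_granularity_mm: float = 2.5
    #: T2 is synthesized on this spacing, then resampled by preprocessing.
    t2_spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 3.0)

    def validate(self) -> None:
        if not 0.0 <= self.shape_irregularity <= 1.0:
            raise ValueError("shape_irregularity must be in [0, 1]")
        if self.tumor_level["dce"] <= self.background_level["dce"]:
            raise ValueError("DCE tumor level must exceed DCE background")
        for name, sd in {**self.noise_sd, **self.texture_amplitude}.items():
            if sd < 0:
                raise ValueError(f"negative sd for {name}")
        if self.tumor_size_mm <= 0:
            raise ValueError("tumor_size_mm must be positive")
        # fit check: tumor bbox + 2 voxel margin per side must fit the grid
        for ax in range(3):
            extent_vox = self.tumor_size_mm / self.spacing_mm[ax]
            # irregularity can push the boundary out by up to ~25 % of radius
            needed = extent_vox * (1.0 + 0.25 * self.shape_irregularity) + 4
            if needed > self.grid_shape[ax]:
                raise PhantomSizingError(
                    f"tumor of {self.tumor_size_mm:.1f} mm does not fit axis "
                    f"{ax} (grid {self.grid_shape[ax]} voxels at "
                    f"{self.spacing_mm[ax]} mm with 2-voxel margin)"
                )

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class ClassEffectProfile:
    """How class labels shift phantom parameters.

    ``effects`` maps a task name to ``{parameter: delta}``; the delta is added
    to the (scalar) spec parameter, scaled by ``effect_size``, when the tumor
    is positive for that task.  With ``effect_size = 0`` the cohort is
    class-exchangeable by construction.  Dict-valued parameters are addressed
    as ``"param.channel"`` (e.g. ``"texture_amplitude.t2"``).
    """

    prevalence: Dict[str, float] = field(
        default_factory=lambda: {"er": 0.75, "pr": 0.65, "her2": 0.20, "histotype": 0.15}
    )
    effects: Dict[str, Dict[str, float]] = field(default_factory=dict)
    effect_size: float = 1.0

    def validate(self) -> None:
        for task, p in self.prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {task} must be in (0,1), got {p}")

    def apply(self, spec: PhantomSpec, labels: Dict[str, Optional[int]]) -> PhantomSpec:
        """Return a spec shifted by the class effects for this tumor's labels."""
        if self.effect_size == 0.0 or not self.effects:
            return spec
        out = spec
        for task, deltas in self.effects.items():
            if labels.get(task) != 1:
                continue
            for param, delta in deltas.items():
                shift = self.effect_size * delta
                if "." in param:
                    name, channel = param.split(".", 1)
                    d = dict(getattr(out, name))
                    d[channel] = d[channel] + shift
                    out = out.replace(**{name: d})
                else:
                    out = out.replace(**{param: getattr(out, param) + shift})
        return out


def _null_profile() -> ClassEffectProfile:
    return ClassEffectProfile(effect_size=0.0)


def er_texture_profile(effect_size: float = 1.0) -> ClassEffectProfile:
    """ER+ tumors get a coarser interior texture (granularity +2 mm per unit
    effect size) in every channel — the canonical injected-signal condition."""
    return ClassEffectProfile(
        effects={"er": {"texture_granularity_mm": 2.0}}, effect_size=effect_size
    )


def er_t2_amplitude_profile(effect_size: float = 1.0) -> ClassEffectProfile:
    """ER-linked effect confined to the T2 channel (texture amplitude +25 per
    unit effect size); DCE and Sub are untouched, so T2-bearing contrast
    combinations should dominate DCE-only models."""
    return ClassEffectProfile(
        effects={"er": {"texture_amplitude.t2": 25.0}}, effect_size=effect_size
    )


# ---------------------------------------------------------------------------
# Mask generation: perturbed ellipsoid with spherical-harmonic boundary noise
# ---------------------------------------------------------------------------


def _boundary_perturbation(
    theta: np.ndarray, phi: np.ndarray, rng: np.random.Generator, max_degree: int = 4
) -> np.ndarray:
    """Smooth zero-mean random function on the sphere, normalized to max |.| 1."""
    out = np.zeros_like(theta)
    for ell in range(1, max_degree + 1):
        for m in range(0, ell + 1):
            a, b = rng.normal(size=2) / (1.0 + ell)
            y = sph_harm_y(ell, m, theta, phi)
            out += a * y.real + (b * y.imag if m > 0 else 0.0)
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


def _voxel_coords_mm(shape, spacing) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def generate_tumor_mask(spec: PhantomSpec, seed: int) -> SegmentationMask:
    """Seeded perturbed-ellipsoid tumor mask.

    The mean of the three bounding-box extents is driven to within ~10 % of
    ``spec.tumor_size_mm`` (one corrective rescale pass).  The region is
    star-shaped about its center, hence connected.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    # mild axis anisotropy, normalized so the mean target extent is preserved
    ratios = np.exp(rng.normal(0.0, 0.12, size=3))
    ratios /= ratios.mean()
    semi = 0.5 * spec.tumor_size_mm * ratios

    x, y, z = _voxel_coords_mm(spec.grid_shape, spec.spacing_mm)
    r = np.sqrt(x * x + y * y + z * z)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, z / np.maximum(r, 1e-12), 1.0), -1, 1))
    phi = np.arctan2(y, x)
    pert = (
        0.25 * spec.shape_irregularity * _boundary_perturbation(theta, phi, rng)
        if spec.shape_irregularity > 0
        else 0.0
    )

    def build(scale: float) -> np.ndarray:
        a, b, c = semi * scale
        rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
        return rho <= 1.0 + pert

    mask = build(1.0)
    m = SegmentationMask(mask, spec.spacing_mm)
    if m.voxel_count == 0:
        raise PhantomSizingError("tumor smaller than one voxel")
    measured = _bbox_mean_extent(m)
    if abs(measured - spec.tumor_size_mm) > 0.08 * spec.tumor_size_mm:
        mask = build(spec.tumor_size_mm / measured)
        m = SegmentationMask(mask, spec.spacing_mm)
    # margin check on the realized mask
    bbox = m.bounding_box()
    for ax, (lo, hi) in enumerate(bbox):
        if lo < 2 or hi > spec.grid_shape[ax] - 3:
            raise PhantomSizingError(
                f"tumor touches the 2-voxel grid margin on axis {ax}"
            )
    return m


def _bbox_mean_extent(mask: SegmentationMask) -> float:
    bbox = mask.bounding_box()
    return float(
        np.mean([(hi - lo + 1) * s for (lo, hi), s in zip(bbox, mask.spacing)])
    )


# ---------------------------------------------------------------------------
# Volume synthesis
# ---------------------------------------------------------------------------


def _correlated_field(
    shape, spacing, granularity_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.normal(size=shape)
    sigma = [max(granularity_mm / s, 1e-6) / 2.0 for s in spacing]
    f = gaussian_filter(white, sigma=sigma, mode="wrap")
    sd = f.std()
    if sd < 1e-9:  # infinite-granularity limit: field is flat
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _channel(
    shape,
    spacing,
    mask: np.ndarray,
    bg: float,
    tum: float,
    noise_sd: float,
    tex_amp: float,
    granularity_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    vol = np.full(shape, bg, dtype=np.float64)
    vol[mask] = tum
    if tex_amp > 0:
        field = _correlated_field(shape, spacing, granularity_mm, rng)
        inside = field[mask]
        sd = inside.std()
        if sd > 1e-9:
            vol[mask] += tex_amp * (inside - inside.mean()) / sd
    if noise_sd > 0:
        vol += rng.normal(0.0, noise_sd, size=shape)
    return vol


def generate_volume_set(
    mask: SegmentationMask,
    spec: PhantomSpec,
    profile: Optional[ClassEffectProfile] = None,
    class_labels: Optional[Dict[str, Optional[int]]] = None,
    seed: int = 0,
) -> VolumeSet:
    """Synthesize DCE, Sub and T2 channels for one tumor.

    Sub = clip(DCE − T1, 0) with a synthesized T1 baseline; T2 lives on its
    own (coarser) grid, with the mask nearest-neighbor-mapped onto it, to make
    downstream resampling do real work.
    """
    if profile is not None and class_labels is not None:
        spec = profile.apply(spec, class_labels)
    spec.validate()
    if mask.shape != tuple(spec.grid_shape):
        raise ValueError("mask grid does not match spec grid")
    rng = np.random.default_rng(seed)
    shape, sp = mask.shape, spec.spacing_mm
    m = mask.data

    dce = _channel(
        shape, sp, m,
        spec.background_level["dce"], spec.tumor_level["dce"],
        spec.noise_sd["dce"], spec.texture_amplitude["dce"],
        spec.texture_granularity_mm, rng,
    )
    t1 = _channel(
        shape, sp, m,
        spec.background_level["t1"], spec.tumor_level["t1"],
        spec.noise_sd["t1"], spec.texture_amplitude["t1"],
        spec.texture_granularity_mm, rng,
    )
    sub = np.clip(dce - t1, 0.0, None)

    # T2 on its own grid: same physical extent, coarser through-plane spacing
    t2_sp = spec.t2_spacing_mm
    t2_shape = tuple(
        max(4, int(round(n * s / ts)))
        for n, s, ts in zip(shape, sp, t2_sp)
    )
    t2_mask = _resample_mask_nearest(m, sp, t2_shape, t2_sp)
    t2 = _channel(
        t2_shape, t2_sp, t2_mask,
        spec.background_level["t2"], spec.tumor_level["t2"],
        spec.noise_sd["t2"], spec.texture_amplitude["t2"],
        spec.texture_granularity_mm, rng,
    )
    return VolumeSet(
        {
            "dce": Volume(dce, sp),
            "sub": Volume(sub, sp),
            "t2": Volume(t2, t2_sp),
        }
    )


def _resample_mask_nearest(mask, spacing, new_shape, new_spacing) -> np.ndarray:
    idx = [
        np.clip(np.round(np.arange(n2) * s2 / s1).astype(int), 0, n1 - 1)
        for n1, s1, n2, s2 in zip(mask.shape, spacing, new_shape, new_spacing)
    ]
    return mask[np.ix_(*idx)]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortPriors:
    """Population-level distributions from which per-tumor specs are drawn.

    The log-normal size law is moment-matched to mean 24.6 mm / SD 16.6 mm
    (median exp(mu) ≈ 20.4 mm); sizes are clipped to [3, 55] mm so every
    tumor fits a modest grid.  ``second_tumor_prob`` targets roughly 1.33
    tumors per patient.
    """

    size_log_mu: float = 3.0153
    size_log_sigma: float = 0.6125
    size_clip_mm: Tuple[float, float] = (3.0, 55.0)
    second_tumor_prob: float = 0.33
    missing_label_fraction: float = 0.05
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 2.0)
    grid_margin_mm: float = 8.0
    irregularity_range: Tuple[float, float] = (0.1, 0.6)
    base_spec: PhantomSpec = field(default_factory=PhantomSpec)

    def draw_size_mm(self, rng: np.random.Generator) -> float:
        s = float(np.exp(rng.normal(self.size_log_mu, self.size_log_sigma)))
        return float(np.clip(s, *self.size_clip_mm))

    def spec_for(self, size_mm: float, rng: np.random.Generator) -> PhantomSpec:
        irr = float(rng.uniform(*self.irregularity_range))
        sp = self.spacing_mm
        shape = tuple(
            int(np.ceil((size_mm * 1.3 + 2 * self.grid_margin_mm) / s))
            for s in sp
        )
        return self.base_spec.replace(
            grid_shape=shape,
            spacing_mm=sp,
            tumor_size_mm=size_mm,
            shape_irregularity=irr,
        )


def plan_cohort(
    n_patients: int,
    priors: Optional[CohortPriors] = None,
    profile: Optional[ClassEffectProfile] = None,
    seed: int = 0,
) -> List[dict]:
    """Draw the per-tumor plan (labels, sizes, specs, seeds) without
    synthesizing any voxel data.  ``generate_cohort`` materializes this plan;
    it is exposed separately so population-level statistics (tumor counts,
    size law, prevalences) can be checked cheaply at full study scale."""
    if n_patients < 10:
        raise ValueError("need at least 10 patients")
    priors = priors or CohortPriors()
    profile = profile or _null_profile()
    profile.validate()
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    plan = []
    tumor_idx = 0
    for p in range(n_patients):
        patient_id = f"P{p:04d}"
        n_tumors = 1 + int(rng.random() < priors.second_tumor_prob)
        for _ in range(n_tumors):
            labels: Dict[str, Optional[int]] = {}
            for task, prev in profile.prevalence.items():
                val = int(rng.random() < prev)
                labels[task] = None if rng.random() < priors.missing_label_fraction else val
            size = priors.draw_size_mm(rng)
            spec = profile.apply(priors.spec_for(size, rng), labels)
            tseed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
            plan.append(
                {
                    "tumor_id": f"T{tumor_idx:04d}",
                    "patient_id": patient_id,
                    "labels": labels,
                    "target_size_mm": size,
                    "spec": spec,
                    "seed": tseed,
                }
            )
            tumor_idx += 1
    return plan


def generate_cohort(
    n_patients: int,
    out_dir: Path,
    priors: Optional[CohortPriors] = None,
    profile: Optional[ClassEffectProfile] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a full phantom cohort on disk and return its table.

    Writes per-tumor NIfTI volumes (`dce`, `sub`, `t2`) and masks, a
    ``cohort.csv`` table and a ``generation.yaml`` record of the parameters.
    Deterministic: the CSV is byte-identical across reruns with the same
    arguments.
    """
    priors = priors or CohortPriors()
    profile = profile or _null_profile()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for item in plan_cohort(n_patients, priors, profile, seed):
        tumor_id = item["tumor_id"]
        patient_id = item["patient_id"]
        labels = item["labels"]
        spec = item["spec"]
        tseed = item["seed"]
        mask = generate_tumor_mask(spec, tseed)
        vs = generate_volume_set(mask, spec, seed=tseed + 1)

        paths = {}
        for c in CONTRASTS:
            path = out_dir / f"{tumor_id}_{c}.nii.gz"
            save_nifti(vs[c].data, vs[c].spacing, path)
            paths[c] = path.name
        mask_path = out_dir / f"{tumor_id}_mask.nii.gz"
        save_nifti(mask.data.astype(np.uint8), mask.spacing, mask_path)

        def lab(task: str) -> str:
            v = labels[task]
            if v is None:
                return ""
            neg, pos = TASKS[task]
            return pos if v == 1 else neg

        rows.append(
            {
                "tumor_id": tumor_id,
                "patient_id": patient_id,
                "er": lab("er"),
                "pr": lab("pr"),
                "her2": lab("her2"),
                "histotype": lab("histotype"),
                "size_mm": round(_bbox_mean_extent(mask), 3),
                "dce_path": paths["dce"],
                "sub_path": paths["sub"],
                "t2_path": paths["t2"],
                "mask_path": mask_path.name,
            }
        )

    table = pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)
    table.to_csv(out_dir / "cohort.csv", index=False, float_format="%.3f")
    record = {
        "seed": int(seed),
        "n_patients": int(n_patients),
        "n_tumors": int(len(table)),
        "priors": _to_plain(priors),
        "profile": _to_plain(profile),
    }
    with open(out_dir / "generation.yaml", "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=True)
    return table


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_cohort(cohort_dir: Path) -> pd.DataFrame:
    """Read a cohort table, validating uniqueness and file existence."""
    cohort_dir = Path(cohort_dir)
    table = pd.read_csv(cohort_dir / "cohort.csv", keep_default_na=False)
    if table["tumor_id"].duplicated().any():
        raise ValueError("duplicate tumor_id in cohort table")
    for col in ("dce_path", "sub_path", "t2_path", "mask_path"):
        for p in table[col]:
            if p and not (cohort_dir / p).exists():
                raise FileNotFoundError(cohort_dir / p)
    return table
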