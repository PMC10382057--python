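"""The radiomic feature inventory: 342 named features in ten categories.

The default inventory allocates features across the classical radiomics
categories — conventional size/shape measurements, statistical moments,
transform-domain (wavelet) summaries, descriptor-based (LBP/gradient)
features, Gabor filter responses, other frequency-domain features, and the
four gray-level texture matrices (GLCM, GLRLM, GLSZM, NGTDM).  The split is
configuration, not code: counts follow from :class:`FeatureConfig` (filter
bank sizes, GLCM distances, FFT band count) and the default sums to exactly
342.  A YAML manifest of the default inventory ships with the package and is
cross-checked in the test suite.

Texture-matrix features depend on the gray-level quantization and are
computed at six level counts (8, 16, 24, 32, 48, 64) then averaged; all
other features are quantization-independent and computed once.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Tuple

import yaml

#: Gray-level counts at which texture matrices are computed then averaged.
QUANTIZATION_LEVELS: Tuple[int, ...] = (8, 16, 24, 32, 48, 64)

#: Categories whose features depend on the gray-level quantization.
QUANT_DEPENDENT_CATEGORIES = frozenset({"glcm", "glrlm", "glszm", "ngtdm"})

GLCM_BASE_FEATURES = [
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

GLRLM_BASE_FEATURES = [
    "sre", "lre", "gln", "rln", "rp",
    "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
]
GLRLM_AGGREGATIONS = ["merged", "dmean", "dstd", "drange"]

GLSZM_FEATURES = [
    "small_zone_emphasis", "large_zone_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_norm", "zone_size_nonuniformity",
    "zone_size_nonuniformity_norm", "zone_percentage",
    "low_gray_zone_emphasis", "high_gray_zone_emphasis",
    "small_zone_low_gray_emphasis", "small_zone_high_gray_emphasis",
    "large_zone_low_gray_emphasis", "large_zone_high_gray_emphasis",
    "gray_level_variance", "zone_size_variance", "zone_entropy",
    "gray_level_mean", "zone_size_mean", "zone_size_max", "zone_count",
    "largest_zone_fraction", "zone_size_entropy", "gray_level_entropy",
    "zone_size_cv", "gray_level_cv", "zone_size_energy",
    "gray_level_energy", "joint_energy",
]

NGTDM_FEATURES = [
    "coarseness", "contrast", "busyness", "complexity", "strength",
    "probability_entropy", "probability_uniformity", "s_sum", "s_mean",
    "s_max", "s_variance", "weighted_s_mean", "occupied_level_fraction",
    "tone_mean", "tone_variance", "tone_skewness",
]

CONVENTIONAL_FEATURES = [
    "volume_mm3", "voxel_count", "surface_area_mm2", "sphericity",
    "compactness1", "compactness2", "spherical_disproportion",
    "bbox_extent_x_mm", "bbox_extent_y_mm", "bbox_extent_z_mm",
    "bbox_volume_mm3", "extent_fraction", "mean_size_mm",
    "max_bbox_extent_mm", "elongation", "flatness", "major_axis_mm",
    "minor_axis_mm", "least_axis_mm", "intensity_mean", "intensity_sd",
    "intensity_variance", "intensity_min", "intensity_max",
    "intensity_range", "intensity_median", "intensity_p10", "intensity_p25",
    "intensity_p75", "intensity_p90",
]

MOMENT_FEATURES = [
    "skewness", "kurtosis", "energy", "entropy", "rms", "mean_abs_dev", "cv",
    "eta_200", "eta_020", "eta_002", "eta_110", "eta_101", "eta_011",
    "eta_300", "eta_030", "eta_003", "eta_111", "j1", "j2", "j3",
]

WAVELET_BANDS = ["aaa", "aad", "ada", "add", "daa", "dad", "dda", "ddd"]
WAVELET_STATS = ["energy_frac", "entropy", "mean_abs"]

DESCRIPTOR_FEATURES = (
    [f"lbp_hist_{i:02d}" for i in range(10)]
    + ["lbp_entropy", "lbp_energy", "lbp_mean", "lbp_var",
       "grad_mag_mean", "grad_mag_sd"]
)

FREQ_SPECTRAL_FEATURES = [
    "spectral_centroid", "spectral_spread", "spectral_entropy",
    "spectral_flatness", "rolloff_85", "high_freq_fraction",
    "low_freq_fraction", "peak_freq",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs that determine the inventory size (default totals 342)."""

    glcm_distances: Tuple[int, ...] = (1, 2, 3)
    gabor_frequencies: Tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4)
    gabor_orientations_deg: Tuple[int, ...] = (0, 45, 90, 135)
    n_freq_bands: int = 16
    quantization_levels: Tuple[int, ...] = QUANTIZATION_LEVELS


@dataclass
class FeatureInventory:
    """Ordered list of (name, category, quantization-dependent) descriptors."""

    names: List[str]
    categories: Dict[str, str]          # name -> category
    quant_dependent: Dict[str, bool]    # name -> depends on quantization

    def __len__(self) -> int:
        return len(self.names)

    def category_names(self) -> List[str]:
        seen: List[str] = []
        for n in self.names:
            c = self.categories[n]
            if c not in seen:
                seen.append(c)
        return seen

    def names_in_category(self, category: str) -> List[str]:
        return [n for n in self.names if self.categories[n] == category]

    def to_manifest(self) -> Dict[str, List[str]]:
        return {c: self.names_in_category(c) for c in self.category_names()}

    def write_manifest(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"n_features": len(self), "categories": self.to_manifest()},
                fh,
                sort_keys=False,
            )


def build_inventory(config: FeatureConfig = FeatureConfig()) -> FeatureInventory:
    """Construct the ordered inventory for a configuration."""
    entries: List[Tuple[str, str]] = []

    for f in CONVENTIONAL_FEATURES:
        entries.append((f"conv_{f}", "conventional"))
    for f in MOMENT_FEATURES:
        entries.append((f"mom_{f}", "moments"))
    for band in WAVELET_BANDS:
        for stat in WAVELET_STATS:
            entries.append((f"wav_{band}_{stat}", "transforms"))
    for f in DESCRIPTOR_FEATURES:
        entries.append((f"desc_{f}", "descriptor"))
    for freq in config.gabor_frequencies:
        for deg in config.gabor_orientations_deg:
            for stat in ("mean", "sd"):
                entries.append((f"gabor_f{freq:g}_t{deg:03d}_{stat}", "gabor"))
    for i in range(config.n_freq_bands):
        entries.append((f"freq_band_energy_{i:02d}", "frequency"))
    for i in range(config.n_freq_bands):
        entries.append((f"freq_band_logpower_{i:02d}", "frequency"))
    for f in FREQ_SPECTRAL_FEATURES:
        entries.append((f"freq_{f}", "frequency"))
    for d in config.glcm_distances:
        for f in GLCM_BASE_FEATURES:
            entries.append((f"glcm_d{d}_{f}", "glcm"))
    for f in GLRLM_BASE_FEATURES:
        for agg in GLRLM_AGGREGATIONS:
            entries.append((f"glrlm_{f}_{agg}", "glrlm"))
    for f in GLSZM_FEATURES:
        entries.append((f"glszm_{f}", "glszm"))
    for f in NGTDM_FEATURES:
        entries.append((f"ngtdm_{f}", "ngtdm"))

    names = [n for n, _ in entries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in inventory")
    categories = {n: c for n, c in entries}
    quant = {n: c in QUANT_DEPENDENT_CATEGORIES for n, c in entries}
    return FeatureInventory(names, categories, quant)


def default_manifest_path() -> Path:
    return Path(str(resources.files("mammotex.features") / "inventory.yaml"))


def load_manifest(path: Path | None = None) -> Dict[str, List[str]]:
    with open(path or default_manifest_path()) as fh:
        doc = yaml.safe_load(fh)
    return doc["categories"]
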