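"""Full-vector extraction: inventory conformance, level averaging,
invariances, and z-score normalization."""

import numpy as np
import pandas as pd
import pytest
import yaml

from mammotex.features import (
    build_inventory,
    extract_features,
    quantize,
    zscore_apply,
    zscore_fit,
)
from mammotex.features.extract import extract_features_single
from mammotex.features.inventory import default_manifest_path, load_manifest
from mammotex.features.matrices import compute_texture_matrices
from mammotex.features.texture import texture_features
from mammotex.synth import PhantomSpec, generate_tumor_mask, generate_volume_set
from mammotex.types import SegmentationMask


@pytest.fixture(scope="module")
def small_case():
    from mammotex.preprocess import harmonize_volume_set

    spec = PhantomSpec(grid_shape=(28, 28, 18), tumor_size_mm=12.0)
    mask = generate_tumor_mask(spec, seed=2)
    vs = generate_volume_set(mask, spec, seed=3)
    vs, mask = harmonize_volume_set(vs, mask)
    return vs, mask


class TestInventory:
    def test_exactly_342_unique_names(self):
        inv = build_inventory()
        assert len(inv) == 342
        assert len(set(inv.names)) == 342

    def test_every_category_nonempty(self):
        inv = build_inventory()
        for cat in ("conventional", "moments", "transforms", "descriptor",
                    "gabor", "frequency", "glcm", "glrlm", "glszm", "ngtdm"):
            assert len(inv.names_in_category(cat)) > 0

    def test_shipped_manifest_matches_default_inventory(self):
        manifest = load_manifest()
        inv = build_inventory()
        assert manifest == inv.to_manifest()


class TestExtraction:
    def test_output_length_and_order(self, small_case):
        vs, mask = small_case
        inv = build_inventory()
        feats = extract_features(vs, mask)
        assert list(feats["dce"].index) == inv.names
        assert len(feats["dce"]) == 342
        assert np.isfinite(feats["dce"].to_numpy()).all()

    def test_level_averaging_equals_external_mean(self, small_case):
        """The averaged GLCM entropy equals the mean of six per-level
        entropies computed independently."""
        vs, mask = small_case
        vec = extract_features_single(vs["dce"].data, mask)
        per_level = []
        for L in (8, 16, 24, 32, 48, 64):
            q = quantize(vs["dce"].data, mask.data, L)
            f = texture_features(compute_texture_matrices(q))
            per_level.append(f["glcm_d1_entropy"])
        assert vec["glcm_d1_entropy"] == pytest.approx(np.mean(per_level), rel=1e-12)

    def test_intensity_shift_leaves_texture_unchanged(self, small_case):
        vs, mask = small_case
        inv = build_inventory()
        a = extract_features_single(vs["dce"].data, mask)
        b = extract_features_single(vs["dce"].data + 500.0, mask)
        quant_names = [n for n in inv.names if inv.quant_dependent[n]]
        assert np.allclose(a[quant_names], b[quant_names], rtol=1e-9)

    def test_axial_rotation_leaves_aggregated_texture_unchanged(self, rng):
        """90-degree in-plane rotation permutes the 13 directions among
        themselves, so direction-aggregated texture features are unchanged."""
        vol = rng.normal(size=(9, 9, 6))
        m = rng.random((9, 9, 6)) < 0.7
        m[4, 4, 3] = True
        inv = build_inventory()
        mask_a = SegmentationMask(m, (1.0, 1.0, 1.0))
        mask_b = SegmentationMask(np.rot90(m, axes=(0, 1)).copy(), (1.0, 1.0, 1.0))
        a = extract_features_single(vol, mask_a)
        b = extract_features_single(np.rot90(vol, axes=(0, 1)).copy(), mask_b)
        quant_names = [n for n in inv.names if inv.quant_dependent[n]]
        assert np.allclose(a[quant_names], b[quant_names], rtol=1e-8)

    def test_missing_contrast_raises(self, small_case):
        vs, mask = small_case
        from mammotex.types import VolumeSet

        broken = VolumeSet({"dce": vs["dce"]})
        with pytest.raises(KeyError):
            extract_features(broken, mask)


class TestZScore:
    def test_fit_rows_have_zero_mean_unit_sd(self, rng):
        X = pd.DataFrame(rng.normal(2.0, 3.0, size=(20, 5)),
                         columns=list("abcde"))
        params = zscore_fit(X)
        Z = zscore_apply(params, X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_row_at_train_mean_maps_to_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        params = zscore_fit(X)
        row = pd.DataFrame([X.mean(axis=0)])
        assert np.allclose(zscore_apply(params, row).to_numpy(), 0.0, atol=1e-12)

    def test_three_row_hand_worked_table(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0], "g": [10.0, 10.0, 10.0]})
        params = zscore_fit(X)
        Z = zscore_apply(params, X)
        sd = np.sqrt(2.0 / 3.0)  # population SD of {1,2,3}
        assert Z["f"].tolist() == pytest.approx([-1 / sd, 0.0, 1 / sd])
        assert (Z["g"] == 0.0).all()  # zero-variance feature flagged to 0
        assert params.zero_sd_features == ["g"]

    def test_params_frozen_for_test_rows(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        params = zscore_fit(X.iloc[:8])
        z_test = zscore_apply(params, X.iloc[8:])
        expected = (X.iloc[8:] - X.iloc[:8].mean()) / X.iloc[:8].std(ddof=0)
        assert np.allclose(z_test.to_numpy(), expected.to_numpy())
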