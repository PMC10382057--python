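"""Mask smoothing, resampling, size measurement and exclusion rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mammotex.preprocess import (
    apply_exclusions,
    resample_to_reference,
    smooth_mask,
    tumor_size_mm,
)
from mammotex.types import DegenerateMaskError, SegmentationMask, Volume


def _mask(arr, spacing=(1.0, 1.0, 1.0)):
    return SegmentationMask(np.asarray(arr, dtype=bool), spacing)


class TestSmoothMask:
    def test_solid_cube_unchanged(self):
        arr = np.zeros((14, 14, 14), dtype=bool)
        arr[2:12, 2:12, 2:12] = True
        out = smooth_mask(_mask(arr))
        assert np.array_equal(out.data, arr)

    def test_single_voxel_spur_removed(self):
        arr = np.zeros((12, 12, 12), dtype=bool)
        arr[3:9, 3:9, 3:9] = True
        spur = arr.copy()
        spur[9, 5, 5] = True  # one voxel sticking out of a face
        out = smooth_mask(_mask(spur))
        assert np.array_equal(out.data, arr)

    def test_isolated_voxel_degenerates(self):
        arr = np.zeros((9, 9, 9), dtype=bool)
        arr[4, 4, 4] = True
        with pytest.raises(DegenerateMaskError):
            smooth_mask(_mask(arr))

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_idempotent_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter

        field = gaussian_filter(rng.normal(size=(16, 16, 16)), 2.0)
        arr = field > np.quantile(field, 0.8)
        try:
            once = smooth_mask(_mask(arr))
        except DegenerateMaskError:
            return
        twice = smooth_mask(once)
        assert np.array_equal(once.data, twice.data)


class TestResample:
    def test_identity_on_matching_grid(self):
        v = Volume(np.random.default_rng(0).normal(size=(8, 8, 8)), (1, 1, 1))
        out = resample_to_reference(v, (8, 8, 8), (1.0, 1.0, 1.0))
        assert np.array_equal(out.data, v.data)

    def test_constant_preserved(self):
        v = Volume(np.full((9, 9, 9), 3.25), (1, 1, 1))
        out = resample_to_reference(v, (5, 5, 5), (2.0, 2.0, 2.0))
        assert np.allclose(out.data, 3.25)

    def test_linear_ramp_matches_closed_form(self):
        # f(x) = 2x (mm) sampled on a 1 mm grid; trilinear interpolation of a
        # linear field is exact, so resampling to 2 mm spacing gives f at the
        # new voxel centers: 2 * (2 * i)
        nx = 17
        x = np.arange(nx, dtype=float)
        vol = np.broadcast_to(2.0 * x[:, None, None], (nx, 5, 5)).copy()
        out = resample_to_reference(Volume(vol, (1, 1, 1)), (8, 5, 5), (2.0, 1.0, 1.0))
        expected = 2.0 * (2.0 * np.arange(8))
        assert np.allclose(out.data[:, 2, 2], expected)

    def test_mask_resample_is_binary(self):
        arr = np.zeros((10, 10, 10), dtype=bool)
        arr[3:7, 3:7, 3:7] = True
        out = resample_to_reference(_mask(arr), (5, 5, 5), (2.0, 2.0, 2.0))
        assert out.data.dtype == bool
        assert out.data.any()


class TestTumorSize:
    def test_solid_box(self):
        arr = np.zeros((40, 40, 40), dtype=bool)
        arr[0:10, 0:20, 0:30] = True
        assert tumor_size_mm(_mask(arr)) == pytest.approx(20.0)
        assert tumor_size_mm(_mask(arr, (0.5, 0.5, 0.5))) == pytest.approx(10.0)

    def test_digital_sphere(self):
        # radius-5 ball -> 11 voxel planes spanned per axis
        g = np.mgrid[-7:8, -7:8, -7:8]
        ball = (g**2).sum(axis=0) <= 25
        assert tumor_size_mm(_mask(ball)) == pytest.approx(11.0)

    def test_translation_invariance_and_spacing_equivariance(self):
        arr = np.zeros((20, 20, 20), dtype=bool)
        arr[2:7, 3:9, 4:11] = True
        shifted = np.roll(arr, (5, 4, 3), axis=(0, 1, 2))
        assert tumor_size_mm(_mask(arr)) == tumor_size_mm(_mask(shifted))
        assert tumor_size_mm(_mask(arr, (2, 2, 2))) == pytest.approx(
            2 * tumor_size_mm(_mask(arr))
        )

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateMaskError):
            tumor_size_mm(_mask(np.zeros((4, 4, 4))))


def _cohort_frame(sizes, t2_paths=None):
    n = len(sizes)
    return pd.DataFrame(
        {
            "tumor_id": [f"T{i}" for i in range(n)],
            "patient_id": [f"P{i}" for i in range(n)],
            "size_mm": sizes,
            "dce_path": ["d.nii.gz"] * n,
            "sub_path": ["s.nii.gz"] * n,
            "t2_path": t2_paths or ["t.nii.gz"] * n,
        }
    )


class TestExclusions:
    def test_minimum_size_is_strict(self):
        kept, log = apply_exclusions(_cohort_frame([4.9, 5.0, 30.0]))
        assert list(kept["size_mm"]) == [5.0, 30.0]
        assert list(log["reason"]) == ["size below minimum"]

    def test_size_window_inclusive(self):
        kept, _ = apply_exclusions(
            _cohort_frame([9.0, 10.0, 20.0, 30.0, 31.0]), size_window=(10.0, 30.0)
        )
        assert list(kept["size_mm"]) == [10.0, 20.0, 30.0]

    def test_missing_contrast_dropped(self):
        frame = _cohort_frame([10.0, 12.0], t2_paths=["t.nii.gz", ""])
        kept, log = apply_exclusions(frame)
        assert list(kept["tumor_id"]) == ["T0"]
        assert log.iloc[0]["reason"] == "missing contrast"

    def test_manual_exclusion_flag(self):
        frame = _cohort_frame([10.0, 12.0]).assign(exclude=[False, True])
        kept, log = apply_exclusions(frame)
        assert list(kept["tumor_id"]) == ["T0"]
        assert log.iloc[0]["reason"] == "manual exclusion"
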