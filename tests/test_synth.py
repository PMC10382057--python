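"""Phantom generator: geometry, determinism, size law, exchangeability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mammotex.preprocess import tumor_size_mm
from mammotex.synth import (
    ClassEffectProfile,
    CohortPriors,
    PhantomSizingError,
    PhantomSpec,
    er_texture_profile,
    generate_tumor_mask,
    generate_volume_set,
    plan_cohort,
)


class TestTumorMask:
    def test_unperturbed_ellipsoid_hits_target_size(self):
        spec = PhantomSpec(tumor_size_mm=20.0, shape_irregularity=0.0)
        mask = generate_tumor_mask(spec, seed=3)
        assert abs(tumor_size_mm(mask) - 20.0) <= 2.0
        # region is a voxelized ellipsoid: convex-ish, one connected blob
        from scipy.ndimage import label

        _, n = label(mask.data)
        assert n == 1

    def test_perturbed_mask_within_ten_percent(self):
        for seed in range(5):
            spec = PhantomSpec(tumor_size_mm=24.0, shape_irregularity=0.6)
            mask = generate_tumor_mask(spec, seed=seed)
            assert abs(tumor_size_mm(mask) - 24.0) <= 0.1 * 24.0

    def test_small_tumor_measures_below_exclusion_threshold(self):
        spec = PhantomSpec(tumor_size_mm=4.0, shape_irregularity=0.0)
        mask = generate_tumor_mask(spec, seed=1)
        assert tumor_size_mm(mask) < 5.0

    def test_determinism(self):
        spec = PhantomSpec()
        a = generate_tumor_mask(spec, seed=42)
        b = generate_tumor_mask(spec, seed=42)
        assert np.array_equal(a.data, b.data)

    def test_does_not_fit_raises(self):
        spec = PhantomSpec(grid_shape=(16, 16, 8), tumor_size_mm=30.0)
        with pytest.raises(PhantomSizingError):
            generate_tumor_mask(spec, seed=0)


class TestVolumeSet:
    def test_noiseless_flat_limit(self):
        spec = PhantomSpec(
            noise_sd={"dce": 0.0, "t1": 0.0, "t2": 0.0},
            texture_amplitude={"dce": 0.0, "t1": 0.0, "t2": 0.0},
        )
        mask = generate_tumor_mask(spec, seed=5)
        vs = generate_volume_set(mask, spec, seed=6)
        inside = vs["dce"].data[mask.data]
        assert np.allclose(inside, spec.tumor_level["dce"])
        outside = vs["dce"].data[~mask.data]
        assert np.allclose(outside, spec.background_level["dce"])

    def test_sub_is_clipped_dce_minus_t1(self):
        spec = PhantomSpec()
        mask = generate_tumor_mask(spec, seed=5)
        vs = generate_volume_set(mask, spec, seed=6)
        assert (vs["sub"].data >= 0).all()
        # tumor clearly enhances on the subtraction channel
        assert vs["sub"].data[mask.data].mean() > vs["sub"].data[~mask.data].mean() + 20

    def test_determinism(self):
        spec = PhantomSpec()
        mask = generate_tumor_mask(spec, seed=5)
        a = generate_volume_set(mask, spec, seed=9)
        b = generate_volume_set(mask, spec, seed=9)
        for c in ("dce", "sub", "t2"):
            assert np.array_equal(a[c].data, b[c].data)

    def test_effect_shifts_only_positive_class(self):
        spec = PhantomSpec()
        prof = er_texture_profile(effect_size=1.0)
        shifted = prof.apply(spec, {"er": 1})
        unshifted = prof.apply(spec, {"er": 0})
        assert shifted.texture_granularity_mm == pytest.approx(4.5)
        assert unshifted.texture_granularity_mm == pytest.approx(2.5)


class TestNullExchangeability:
    def test_mean_intensity_exchangeable_when_effect_zero(self, rng):
        """With effect_size = 0 a class-conditional statistic is exchangeable:
        the observed between-class difference is not extreme among 200 label
        permutations (alpha = 0.01)."""
        spec = PhantomSpec(grid_shape=(24, 24, 16), tumor_size_mm=12.0)
        profile = ClassEffectProfile(
            effects={"er": {"texture_granularity_mm": 3.0}}, effect_size=0.0
        )
        stats_, labels = [], []
        for i in range(40):
            lab = {"er": int(rng.random() < 0.5)}
            sp = profile.apply(spec, lab)
            mask = generate_tumor_mask(sp, seed=1000 + i)
            vs = generate_volume_set(mask, sp, seed=2000 + i)
            stats_.append(float(vs["dce"].data[mask.data].std()))
            labels.append(lab["er"])
        stats_ = np.array(stats_)
        labels = np.array(labels)
        obs = abs(stats_[labels == 1].mean() - stats_[labels == 0].mean())
        perm = []
        for _ in range(200):
            sh = rng.permutation(labels)
            perm.append(abs(stats_[sh == 1].mean() - stats_[sh == 0].mean()))
        p = (1 + sum(v >= obs for v in perm)) / 201
        assert p > 0.01


class TestCohortPlan:
    def test_tumor_count_near_study_ratio(self):
        """323 patients yield on the order of 429 tumors (multiplicity prior)."""
        plan = plan_cohort(323, seed=17)
        assert 390 <= len(plan) <= 470

    def test_size_law_mean_median(self):
        priors = CohortPriors()
        rng = np.random.default_rng(3)
        sizes = np.array([priors.draw_size_mm(rng) for _ in range(429)])
        assert abs(sizes.mean() - 24.6) / 24.6 < 0.15
        assert abs(np.median(sizes) - 20.3) / 20.3 < 0.15
        assert 17.0 <= np.median(sizes) <= 24.0

    def test_size_law_ks_distance(self):
        priors = CohortPriors()
        rng = np.random.default_rng(4)
        sizes = np.array([priors.draw_size_mm(rng) for _ in range(429)])
        # compare against the configured (unclipped) log-normal law
        d, _ = stats.kstest(
            sizes, lambda x: stats.lognorm.cdf(x, priors.size_log_sigma,
                                               scale=np.exp(priors.size_log_mu))
        )
        assert d < 0.1

    def test_missing_labels_and_prevalence(self):
        plan = plan_cohort(300, seed=8)
        er = [t["labels"]["er"] for t in plan]
        missing = sum(v is None for v in er) / len(er)
        assert 0.01 < missing < 0.12
        present = [v for v in er if v is not None]
        assert 0.65 < np.mean(present) < 0.85

    def test_plan_determinism(self):
        a = plan_cohort(30, seed=9)
        b = plan_cohort(30, seed=9)
        assert [t["seed"] for t in a] == [t["seed"] for t in b]
        assert [t["target_size_mm"] for t in a] == [t["target_size_mm"] for t in b]


class TestGenerateCohort:
    def test_csv_byte_identical_across_reruns(self, tmp_path):
        from mammotex.synth import generate_cohort

        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(10, d1, seed=31)
        generate_cohort(10, d2, seed=31)
        assert (d1 / "cohort.csv").read_bytes() == (d2 / "cohort.csv").read_bytes()

    def test_cohort_files_exist_and_load(self, base_cohort):
        from mammotex.synth import load_cohort

        table = load_cohort(base_cohort["dir"])
        assert table["tumor_id"].is_unique
        assert len(table) >= 40
        # some patients own two tumors
        assert (table.groupby("patient_id").size() > 1).any()
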