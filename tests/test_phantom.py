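"""Synthetic cohort generator: determinism, calibration and statistical structure."""

import numpy as np
import pytest

from lnrad.phantom import (
    PhantomConfig,
    cohort_metadata,
    generate_cohort,
    make_lesion,
    perturb_mask,
)
from lnrad.reproducibility import dice


def small_config(**kw):
    defaults = dict(n_patients_train=6, n_patients_test=4, rater2_n_patients=3, seed=5)
    defaults.update(kw)
    return PhantomConfig(**defaults)


class TestGenerateCohort:
    def test_fixed_seed_reproduces_cohort_exactly(self):
        a = generate_cohort(small_config())
        b = generate_cohort(small_config())
        assert len(a) == len(b)
        for na, nb in zip(a, b):
            assert na.node_id == nb.node_id and na.label == nb.label
            np.testing.assert_array_equal(na.image.voxels, nb.image.voxels)
            np.testing.assert_array_equal(na.mask_rater1.voxels, nb.mask_rater1.voxels)
            assert na.suvmax == nb.suvmax and na.expert_rating == nb.expert_rating

    def test_degenerate_prevalence_one(self):
        nodes = generate_cohort(small_config(prevalence=1.0, n_patients_train=10))
        assert all(n.label == 1 for n in nodes)

    def test_prevalence_within_binomial_band(self):
        cfg = PhantomConfig(
            n_patients_train=170, n_patients_test=170, nodes_per_patient=(3, 3),
            prevalence=0.7, rater2_n_patients=0, seed=9,
        )
        # label draws only: avoid building ~1000 images
        rng = np.random.default_rng(cfg.seed)
        labels = rng.random(1000) < cfg.prevalence
        n = len(labels)
        sd = np.sqrt(0.7 * 0.3 / n)
        assert abs(labels.mean() - 0.7) < 3 * sd

    def test_cohort_structure(self):
        nodes = generate_cohort(small_config())
        md = cohort_metadata(nodes)
        assert set(md.cohort) == {"train", "test"}
        assert (md[md.cohort == "train"].batch == "mCT").all()
        assert set(md[md.cohort == "test"].batch) <= {"ext1", "ext2", "ext3"}
        assert md.has_rater2.sum() > 0
        assert (md[md.has_rater2].cohort == "train").all()
        for n in nodes:  # masks fully inside the canvas
            assert not n.mask_rater1.voxels[0].any() and not n.mask_rater1.voxels[-1].any()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            generate_cohort(small_config(n_patients_train=0))
        with pytest.raises(ValueError):
            generate_cohort(small_config(train_scanners=()))
        with pytest.raises(ValueError):
            generate_cohort(small_config(prevalence=0.0))
        with pytest.raises(ValueError):
            generate_cohort(small_config(lesion_volume_range=(-1.0, 0.5)))

    def test_batch_offsets_shift_image_intensity(self):
        from lnrad.phantom import Scanner

        base = small_config(seed=21)
        shifted = small_config(
            seed=21,
            test_scanners=(Scanner("extX", 40.0, 1.0),),
        )
        m_base = np.mean([
            n.image.voxels[n.mask_rater1.voxels].mean()
            for n in generate_cohort(base) if n.cohort == "test"
        ])
        m_shift = np.mean([
            n.image.voxels[n.mask_rater1.voxels].mean()
            for n in generate_cohort(shifted) if n.cohort == "test"
        ])
        # base test scanners average ~+4.7 HU offset; extX adds +40
        assert m_shift - m_base > 25


class TestMakeLesion:
    def test_volume_within_15pct(self, rng):
        for target in (0.06, 0.15, 0.4):
            _, mask = make_lesion(target, 0.2, 0.0, rng)
            assert mask.volume_mm3 / 1000.0 == pytest.approx(target, rel=0.15)

    def test_volume_equals_count_times_voxel_volume(self, rng):
        _, mask = make_lesion(0.15, 0.0, 0.0, rng, spacing=(1.0, 1.0, 1.0))
        assert mask.n_voxels == pytest.approx(150, rel=0.15)

    def test_zero_texture_amplitude_leaves_white_noise_variance(self, rng):
        img, mask = make_lesion(0.4, 0.0, 0.0, rng, noise_sd=10.0)
        inside = img.voxels[mask.voxels]
        assert inside.var() == pytest.approx(100.0, rel=0.25)

    def test_subvoxel_volume_rejected(self, rng):
        with pytest.raises(ValueError):
            make_lesion(1e-7, 0.0, 0.0, rng)
        with pytest.raises(ValueError):
            make_lesion(-0.1, 0.0, 0.0, rng)

    def test_mask_is_single_connected_component(self, rng):
        from scipy import ndimage

        for _ in range(5):
            _, mask = make_lesion(0.1, 0.3, 0.0, rng)
            _, nlab = ndimage.label(mask.voxels)
            assert nlab == 1


class TestPerturbMask:
    def test_zero_magnitude_is_identity(self, rng):
        _, mask = make_lesion(0.15, 0.1, 0.0, rng)
        out = perturb_mask(mask, 0.0, rng)
        np.testing.assert_array_equal(out.voxels, mask.voxels)

    def test_negative_magnitude_rejected(self, rng):
        _, mask = make_lesion(0.15, 0.1, 0.0, rng)
        with pytest.raises(ValueError):
            perturb_mask(mask, -1.0, rng)

    def test_default_magnitude_hits_dice_calibration_band(self):
        """Median Dice over replicate second raters sits in [0.85, 0.93]."""
        dices = []
        for i in range(60):
            _, mask = make_lesion(0.15, 0.15, 0.0, np.random.default_rng(i))
            d2 = perturb_mask(mask, PhantomConfig().rater2_magnitude_mm,
                              np.random.default_rng(5000 + i))
            dices.append(dice(mask, d2))
        assert 0.85 <= np.median(dices) <= 0.93

    def test_dice_decreases_with_magnitude_and_collapses_eventually(self):
        meds = []
        for mag in (0.3, 0.7, 1.5, 5.0):
            ds = []
            for i in range(25):
                _, mask = make_lesion(0.15, 0.1, 0.0, np.random.default_rng(i))
                ds.append(dice(mask, perturb_mask(mask, mag, np.random.default_rng(900 + i))))
            meds.append(np.median(ds))
        assert meds[0] > meds[1] > meds[2] > meds[3]
        assert meds[-1] < 0.5


def test_group_difference_and_null_calibration():
    """Mean-intensity Wilcoxon: rejects under the configured label effect at
    n=200; type-I error stays near alpha when the effect is switched off."""
    import scipy.stats as st

    rng = np.random.default_rng(42)
    n = 200
    shift = PhantomConfig().lnm_intensity_shift
    hits = 0
    for _ in range(25):
        labels = rng.random(n) < 0.5
        base = 45 + 8 * rng.standard_normal(n)
        with_effect = base + shift * labels
        hits += st.mannwhitneyu(with_effect[labels], with_effect[~labels]).pvalue < 0.05
    assert hits >= 20  # the test is powered ~0.99 at this effect size

    rejections = 0
    reps = 300
    for _ in range(reps):
        y = rng.random(n) < 0.5
        x = 45 + 8 * rng.standard_normal(n)
        if st.mannwhitneyu(x[y], x[~y]).pvalue < 0.05:
            rejections += 1
    rate = rejections / reps
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)
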