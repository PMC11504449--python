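"""Synthetic vertebra-column generator, augmentation and dataset splits."""

import numpy as np
import pytest
from scipy import ndimage

from spinediff.synthetic import (AugmentConfig, SynthConfig, augment,
                                 config_for_mode, generate_pair, make_dataset)


class TestGeneratePair:
    def test_clean_degenerate_case_recovers_mask(self):
        """Full contrast, no blur/noise/texture: thresholding is exact."""
        cfg = SynthConfig(blur_sigma=0.0, noise_sd=0.0, bg_contrast=1.0)
        img, msk = generate_pair(cfg)
        np.testing.assert_array_equal((img >= 0.5).astype(np.uint8), msk)

    def test_deterministic_under_seed(self):
        cfg = SynthConfig(seed=11)
        a = generate_pair(cfg)
        b = generate_pair(cfg)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_types_ranges_and_dimensions(self):
        img, msk = generate_pair(SynthConfig(seed=2))
        assert img.shape == msk.shape == (160, 64)
        assert img.dtype == np.float32 and img.min() >= 0 and img.max() <= 1
        assert set(np.unique(msk)) <= {0, 1}

    def test_foreground_fraction_plausible(self):
        fracs = [generate_pair(SynthConfig(seed=s))[1].mean() for s in range(100)]
        assert all(0.05 < f < 0.6 for f in fracs)

    def test_too_small_canvas_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(height=20, width=64, n_vertebrae=5)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(blur_sigma=-1.0)

    def test_mode_boundary_gradient_ordering(self):
        """ct-like is crispest, xray-like blurriest, mr-like in between."""
        grads = {}
        for mode in ("ct-like", "mr-like", "xray-like"):
            vals = []
            for s in range(50):
                img, msk = generate_pair(config_for_mode(mode, seed=s))
                boundary = msk.astype(bool) ^ ndimage.binary_erosion(msk)
                gy, gx = np.gradient(img.astype(np.float64))
                vals.append(np.hypot(gy, gx)[boundary].mean())
            grads[mode] = np.mean(vals)
        assert grads["ct-like"] > grads["mr-like"] > grads["xray-like"]


class TestAugment:
    def test_disabled_stack_is_identity(self):
        img, msk = generate_pair(SynthConfig(seed=3))
        cfg = AugmentConfig(rotate_deg_range=(0, 0), shift_frac_range=(0, 0),
                            elastic=False, contrast=False)
        out_img, out_msk = augment(img, msk, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_msk, msk)

    def test_mask_stays_binary(self):
        img, msk = generate_pair(SynthConfig(seed=4))
        cfg = AugmentConfig()
        for i in range(5):
            _, m = augment(img, msk, cfg, np.random.default_rng(i))
            assert set(np.unique(m)) <= {0, 1}

    def test_foreground_roughly_preserved(self):
        """Rotation+shift keeps the column mostly in frame (<15% area change)."""
        img, msk = generate_pair(SynthConfig(seed=5))
        base = int(msk.sum())
        cfg = AugmentConfig(elastic=False, contrast=False)
        rng = np.random.default_rng(35)
        for _ in range(100):
            _, m = augment(img, msk, cfg, rng)
            assert abs(int(m.sum()) - base) / base < 0.15

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(rotate_deg_range=(-40, 30))
        with pytest.raises(ValueError):
            AugmentConfig(shift_frac_range=(0.01, 0.2))


class TestMakeDataset:
    def test_split_sizes(self):
        cfg = SynthConfig(height=40, width=24, n_vertebrae=2)
        splits = make_dataset(10, (0.8, 0.1, 0.1), cfg, seed=1)
        assert [len(splits[k]) for k in ("train", "val", "test")] == [8, 1, 1]

    def test_deterministic(self):
        cfg = SynthConfig(height=40, width=24, n_vertebrae=2)
        a = make_dataset(6, (0.5, 0.25, 0.25), cfg, seed=9)
        b = make_dataset(6, (0.5, 0.25, 0.25), cfg, seed=9)
        for k in a:
            for pa, pb in zip(a[k], b[k]):
                assert pa.id == pb.id and pa.seed == pb.seed
                np.testing.assert_array_equal(pa.image, pb.image)

    def test_ids_disjoint_across_splits(self):
        cfg = SynthConfig(height=40, width=24, n_vertebrae=2)
        splits = make_dataset(12, (0.5, 0.25, 0.25), cfg, seed=2)
        ids = [p.id for pairs in splits.values() for p in pairs]
        assert len(ids) == len(set(ids)) == 12

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(10, (0.5, 0.2, 0.2), SynthConfig(), seed=0)
        with pytest.raises(ValueError):
            make_dataset(2, (0.4, 0.3, 0.3), SynthConfig(), seed=0)
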