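"""Windowing, patch extraction and paired affine augmentation."""

import numpy as np
import pytest

from synthce.ctdata import (AffineParams, PatchSample, augment_supervised,
                            denormalise, extract_patches, window_normalise)


class TestWindowing:
    @pytest.mark.parametrize("hu,expected", [
        (-500.0, 0.0), (2500.0, 1.0), (1000.0, 0.5), (3000.0, 1.0),
        (-900.0, 0.0),
    ])
    def test_default_window_mapping(self, hu, expected):
        wv = window_normalise(np.full((2, 2, 2), hu))
        assert wv.data == pytest.approx(expected)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            window_normalise(np.zeros((2, 2, 2)), low=100, high=100)
        with pytest.raises(ValueError):
            window_normalise(np.full((2, 2, 2), np.nan))

    @pytest.mark.parametrize("norm,hu", [(0.0, -500.0), (1.0, 2500.0),
                                         (0.5, 1000.0)])
    def test_denormalise_inverts_window(self, norm, hu):
        wv = window_normalise(np.full((2, 2, 2), hu))
        wv.data[:] = norm
        assert denormalise(wv) == pytest.approx(hu)

    def test_round_trip_identity_on_unit_interval(self, rng):
        values = rng.random((100,))
        wv = window_normalise(np.zeros((4, 5, 5)))
        wv.data = values.reshape(4, 5, 5)[:4]
        hu = denormalise(wv)
        back = window_normalise(hu)
        assert np.abs(back.data - wv.data).max() < 1e-9

    def test_monotone_within_window(self, rng):
        hu = rng.uniform(-500, 2500, size=(4, 4, 4))
        wv = window_normalise(hu)
        flat_in = hu.ravel()
        flat_out = wv.data.ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= 0).all()


class TestExtractPatches:
    def _volumes(self, shape=(16, 16, 16)):
        rng = np.random.default_rng(0)
        src = window_normalise(rng.uniform(-500, 2500, shape))
        tgt = window_normalise(rng.uniform(-500, 2500, shape))
        mask = np.zeros(shape, dtype=np.int16)
        mask[4:8, 4:8, 4:8] = 1
        return src, tgt, mask

    def test_patch_equal_to_volume_has_single_origin(self):
        src, tgt, mask = self._volumes()
        samples = extract_patches(src, tgt, mask, n=3, patch_size=16)
        assert all(s.origin == (0, 0, 0) for s in samples)

    def test_origins_respect_bounds(self):
        src, tgt, mask = self._volumes()
        samples = extract_patches(src, tgt, mask, n=50, patch_size=8,
                                  rng_seed=5)
        for s in samples:
            assert all(0 <= o and o + 8 <= 16 for o in s.origin)
            assert s.source_patch.shape == s.target_patch.shape \
                == s.mask_patch.shape == (8, 8, 8)

    def test_seeded_determinism(self):
        src, tgt, mask = self._volumes()
        a = extract_patches(src, tgt, mask, n=20, patch_size=8, rng_seed=9)
        b = extract_patches(src, tgt, mask, n=20, patch_size=8, rng_seed=9)
        assert [s.origin for s in a] == [s.origin for s in b]

    def test_oversized_patch_rejected(self):
        src, tgt, mask = self._volumes()
        with pytest.raises(ValueError):
            extract_patches(src, tgt, mask, n=1, patch_size=32)

    def test_foreground_bias_finds_labelled_voxels(self):
        src, tgt, mask = self._volumes()
        samples = extract_patches(src, tgt, mask, n=40, patch_size=8,
                                  rng_seed=2, foreground_bias=1.0)
        assert all((s.mask_patch > 0).any() for s in samples)


class TestAugment:
    def _sample(self, seed=0, size=12):
        rng = np.random.default_rng(seed)
        src = rng.random((size, size, size))
        tgt = rng.random((size, size, size))
        mask = (rng.random((size, size, size)) > 0.8).astype(np.int16)
        return PatchSample(src, tgt, mask, (0, 0, 0), phase=1)

    def test_identity_transform_is_noop(self):
        s = self._sample()
        out = augment_supervised(s, params=AffineParams())
        assert np.allclose(out.source_patch, s.source_patch)
        assert np.allclose(out.target_patch, s.target_patch)
        assert (out.mask_patch == s.mask_patch).all()

    def test_flip_preserves_mask_label_multiset(self):
        s = self._sample()
        out = augment_supervised(
            s, params=AffineParams(flips=(True, False, True)))
        assert np.bincount(out.mask_patch.ravel()).tolist() \
            == np.bincount(s.mask_patch.ravel()).tolist()

    def test_source_and_target_share_displacement_field(self):
        """Transforming an identical coordinate-ramp volume as both source
        and target must give identical outputs for any drawn transform."""
        size = 12
        grid = np.mgrid[0:size, 0:size, 0:size]
        ramp = (grid[0] + 2 * grid[1] + 3 * grid[2]) / (6.0 * size)
        mask = np.zeros((size, size, size), dtype=np.int16)
        s = PatchSample(ramp.copy(), ramp.copy(), mask, (0, 0, 0))
        for seed in range(5):
            out = augment_supervised(s, rng_seed=seed)
            assert np.array_equal(out.source_patch, out.target_patch)

    def test_intensities_stay_in_unit_interval(self):
        s = self._sample()
        out = augment_supervised(s, rng_seed=3)
        assert out.source_patch.min() >= 0.0
        assert out.source_patch.max() <= 1.0
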