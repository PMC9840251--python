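import numpy as np
import pytest

from rodentseg.preprocess import (PatchGrid, apply_ops, augment,
                                  central_crop_or_pad, normalize_intensity,
                                  patchify, random_ops, resample_isotropic,
                                  resample_mask_isotropic, unpatchify)
from rodentseg.volio import Mask, ModalityStack, Volume


def _vol(data, spacing=(0.5, 0.5, 0.5)):
    return Volume(np.asarray(data, dtype=np.float32), spacing)


class TestNormalize:
    def test_minmax255_range(self, rng):
        v = _vol(rng.normal(10, 5, (8, 8, 8)))
        out = normalize_intensity(v, "minmax255")
        assert out.data.min() == pytest.approx(0.0)
        assert out.data.max() == pytest.approx(255.0)

    def test_zscore_moments(self, rng):
        out = normalize_intensity(_vol(rng.normal(7, 3, (10, 10, 10))), "zscore")
        assert abs(out.data.mean()) < 1e-6
        assert abs(out.data.std() - 1) < 1e-6

    def test_zscore_affine_invariance(self, rng):
        data = rng.normal(size=(8, 8, 8))
        a = normalize_intensity(_vol(data), "zscore")
        b = normalize_intensity(_vol(3.5 * data + 11.0), "zscore")
        np.testing.assert_allclose(a.data, b.data, atol=1e-5)

    def test_constant_volume_handling(self, caplog):
        const = _vol(np.full((4, 4, 4), 3.0))
        with pytest.raises(ValueError):
            normalize_intensity(const, "zscore")
        with caplog.at_level("WARNING", logger="rodentseg"):
            out = normalize_intensity(const, "minmax255")
        assert np.all(out.data == 0)


class TestResample:
    def test_shape_formula_on_rat_lattice(self):
        """192x192x80 at 0.29/0.29/0.43 mm resamples to 111x111x69 at 0.5 mm."""
        v = _vol(np.zeros((80, 192, 192)), spacing=(0.43, 0.29, 0.29))
        out = resample_isotropic(v, 0.5)
        assert out.shape == (69, 111, 111)
        assert out.spacing == (0.5, 0.5, 0.5)

    def test_constant_volume_downsampling(self):
        v = _vol(np.full((40, 40, 40), 7.0), spacing=(0.25, 0.25, 0.25))
        out = resample_isotropic(v, 0.5)
        assert out.shape == (20, 20, 20)
        np.testing.assert_allclose(out.data, 7.0, atol=1e-5)

    def test_linear_ramp_reproduced(self):
        """Cubic-spline resampling is exact on a trilinear ramp (interior)."""
        z, y, x = np.meshgrid(np.arange(24) * 0.4, np.arange(24) * 0.4,
                              np.arange(24) * 0.4, indexing="ij")
        ramp = 2.0 * z + 0.5 * y - 1.5 * x + 3.0
        out = resample_isotropic(_vol(ramp, (0.4, 0.4, 0.4)), 0.5)
        zo, yo, xo = np.meshgrid(np.arange(out.shape[0]) * 0.5,
                                 np.arange(out.shape[1]) * 0.5,
                                 np.arange(out.shape[2]) * 0.5, indexing="ij")
        expected = 2.0 * zo + 0.5 * yo - 1.5 * xo + 3.0
        core = (slice(3, -3),) * 3
        scale = np.maximum(np.abs(expected[core]), 1.0)
        rel = np.abs(out.data[core] - expected[core]) / scale
        assert rel.max() < 1e-3

    def test_mask_stays_binary(self, rng):
        m = Mask((rng.random((20, 20, 20)) < 0.4).astype(np.uint8),
                 (0.3, 0.3, 0.3))
        for mode in ("nearest", "linear"):
            out = resample_mask_isotropic(m, 0.5, mask_mode=mode)
            assert set(np.unique(out.labels)) <= {0, 1}

    def test_bad_target(self):
        with pytest.raises(ValueError):
            resample_isotropic(_vol(np.zeros((4, 4, 4))), 0.0)


class TestCropPad:
    def test_mixed_crop_and_pad(self, rng):
        v = _vol(rng.normal(size=(69, 111, 111)))
        out = central_crop_or_pad(v, (64, 128, 128))
        assert out.shape == (64, 128, 128)
        # z cropped centrally, y/x zero-padded
        np.testing.assert_array_equal(out.data[:, 8:119, 8:119],
                                      v.data[2:66, :, :])
        assert np.all(out.data[:, :8, :] == 0)

    def test_identity_and_round_trip(self, rng):
        v = _vol(rng.normal(size=(10, 12, 14)))
        same = central_crop_or_pad(v, (10, 12, 14))
        np.testing.assert_array_equal(same.data, v.data)
        padded = central_crop_or_pad(v, (16, 16, 16))
        back = central_crop_or_pad(padded, (10, 12, 14))
        np.testing.assert_array_equal(back.data, v.data)

    def test_mask_padded_with_zero(self):
        m = Mask(np.ones((4, 4, 4), np.uint8), (1, 1, 1))
        out = central_crop_or_pad(m, (8, 8, 8))
        assert out.count() == 64


class TestPatchify:
    def test_tiling_counts(self, rng):
        stack = rng.normal(size=(3, 64, 128, 128)).astype(np.float32)
        grid = patchify(stack, 64)
        assert len(grid.patches) == 4  # 1*2*2 tiles of the rat matrix
        single = patchify(rng.normal(size=(3, 64, 64, 64)), 64)
        assert len(single.patches) == 1
        np.testing.assert_array_equal(single.patches[0], single.patches[0])

    def test_round_trip_bit_exact(self, rng):
        stack = rng.normal(size=(3, 32, 64, 32)).astype(np.float32)
        grid = patchify(stack, 16)
        np.testing.assert_array_equal(unpatchify(grid), stack)

    def test_non_divisible_rejected(self, rng):
        with pytest.raises(ValueError, match="crop/pad|divisible"):
            patchify(rng.normal(size=(3, 60, 64, 64)), 64)

    def test_overlapping_origins_rejected(self, rng):
        grid = patchify(rng.normal(size=(3, 32, 32, 32)), 16)
        with pytest.raises(ValueError, match="overlap"):
            PatchGrid(patches=grid.patches,
                      origins=[grid.origins[0]] * len(grid.origins),
                      source_shape=grid.source_shape, patch=grid.patch)

    def test_block_reassembly(self):
        patches = [np.full((1, 2, 2, 2), v, dtype=np.float32) for v in (1, 2, 3, 4)]
        grid = PatchGrid(patches=patches,
                         origins=[(0, 0, 0), (0, 0, 2), (0, 2, 0), (0, 2, 2)],
                         source_shape=(2, 4, 4), patch=2)
        out = unpatchify(grid)
        assert out[0, 0, 0, 0] == 1 and out[0, 0, 3, 3] == 4


class TestAugment:
    def _stack_and_masks(self, rng, shape=(8, 8, 8)):
        stack = ModalityStack.from_array(
            rng.normal(size=(3,) + shape).astype(np.float32), (0.5, 0.5, 0.5))
        brain = Mask((rng.random(shape) < 0.6).astype(np.uint8), (0.5, 0.5, 0.5))
        tumor = Mask((brain.labels & (rng.random(shape) < 0.3)).astype(np.uint8),
                     (0.5, 0.5, 0.5))
        return stack, brain, tumor

    def test_flip_involution_and_rot_cycle(self, rng):
        arr = rng.normal(size=(4, 6, 6))
        np.testing.assert_array_equal(
            apply_ops(apply_ops(arr, [("flip", 1)]), [("flip", 1)]), arr)
        np.testing.assert_array_equal(apply_ops(arr, [("rot90", 0, 4)]), arr)

    def test_value_multiset_preserved(self, rng):
        stack, brain, tumor = self._stack_and_masks(rng)
        out_stack, out_brain, out_tumor = augment(stack, brain, tumor, seed=5)
        for a, b in zip(stack.volumes, out_stack.volumes):
            np.testing.assert_array_equal(np.sort(a.data, axis=None),
                                          np.sort(b.data, axis=None))
        assert out_brain.count() == brain.count()

    def test_subset_relation_preserved(self, rng):
        stack, brain, tumor = self._stack_and_masks(rng)
        for seed in range(8):
            _, ob, ot = augment(stack, brain, tumor, seed=seed)
            assert np.all(ot.labels <= ob.labels)

    def test_identical_transform_on_channels_and_masks(self, rng):
        stack, brain, tumor = self._stack_and_masks(rng)
        ops = [("rot90", 0, 1), ("flip", 2)]
        out_stack, out_brain, _ = augment(stack, brain, tumor, ops=ops)
        np.testing.assert_array_equal(out_stack.t1.data,
                                      apply_ops(stack.t1.data, ops))
        np.testing.assert_array_equal(out_brain.labels,
                                      apply_ops(brain.labels, ops))

    def test_rot90_needs_square_plane(self, rng):
        arr = rng.normal(size=(4, 6, 8))
        with pytest.raises(ValueError, match="equal dims"):
            apply_ops(arr, [("rot90", 0, 1)])

    def test_random_ops_deterministic(self):
        assert random_ops(99) == random_ops(99)
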