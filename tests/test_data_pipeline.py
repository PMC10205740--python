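import numpy as np
import pytest

from epiderm import data_pipeline as dp


class TestDownsample:
    def test_full_slide_factor_four(self):
        img = np.zeros((1040, 1384, 3), np.uint8)
        assert dp.downsample(img, 4, "image").shape == (260, 346, 3)

    def test_factor_one_is_identity(self, rng):
        img = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)
        assert np.array_equal(dp.downsample(img, 1, "image"), img)

    def test_mask_label_set_preserved(self, rng):
        mask = rng.integers(0, 3, (33, 47)).astype(np.uint8)
        out = dp.downsample(mask, 2, "mask")
        assert out.shape == (17, 24)
        assert set(np.unique(out)) <= {0, 1, 2}

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            dp.downsample(np.zeros((4, 4)), 0, "image")


class TestAugment:
    def test_neutral_policy_is_identity(self, rng):
        img = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)
        mask = rng.integers(0, 3, (16, 16)).astype(np.uint8)
        policy = dp.AugmentPolicy(flips=False, brightness_range=(1.0, 1.0),
                                  rotation_deg=(0.0, 0.0))
        assert policy.neutral
        out_img, out_mask = dp.augment(img, mask, policy, rng=0)
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_mask, mask)

    def test_flip_is_involution(self, rng):
        img = rng.integers(0, 255, (8, 8, 3)).astype(np.uint8)
        assert np.array_equal(img[::-1][::-1], img)
        assert np.array_equal(img[:, ::-1][:, ::-1], img)

    def test_brightness_draws_within_range(self):
        policy = dp.AugmentPolicy(flips=False, brightness_range=(0.75, 1.25))
        img = np.full((4, 4, 3), 100, np.uint8)
        factors = []
        master = np.random.default_rng(0)
        for _ in range(1000):
            out, _ = dp.augment(img, None, policy, np.random.default_rng(
                master.integers(2 ** 31)))
            factors.append(out.astype(float).mean() / 100.0)
        assert min(factors) >= 0.75 - 0.01 and max(factors) <= 1.25 + 0.01
        # mean of 1000 uniform(0.75, 1.25) draws: se ~ 0.005, plus rounding
        assert np.mean(factors) == pytest.approx(1.0, abs=0.02)

    def test_geometry_shared_between_image_and_mask(self):
        img = np.zeros((16, 16, 3), np.uint8)
        mask = np.zeros((16, 16), np.uint8)
        img[2, 3] = 255
        mask[2, 3] = 2
        policy = dp.AugmentPolicy(flips=True, brightness_range=(1.0, 1.0))
        out_img, out_mask = dp.augment(img, mask, policy, rng=3)
        marked = np.argwhere(out_mask == 2)
        assert len(marked) == 1
        r, c = marked[0]
        assert out_img[r, c, 0] == 255

    def test_mask_shape_mismatch(self):
        with pytest.raises(ValueError):
            dp.augment(np.zeros((8, 8, 3), np.uint8), np.zeros((4, 4), np.uint8),
                       dp.AugmentPolicy(), rng=0)


class TestSamplePatches:
    def test_count_and_bounds(self, rng):
        img = rng.integers(0, 255, (40, 50, 3)).astype(np.uint8)
        spec = dp.PatchSpec(size_px=16, stride_px=16, count=32, seed=1)
        patches = dp.sample_patches(img, None, spec)
        assert len(patches) == 32
        for patch, _, (r, c) in patches:
            assert patch.shape == (16, 16, 3)
            assert 0 <= r <= 24 and 0 <= c <= 34

    def test_deterministic_origins(self, rng):
        img = rng.integers(0, 255, (40, 40, 3)).astype(np.uint8)
        spec = dp.PatchSpec(size_px=8, stride_px=8, count=10, seed=5)
        a = [o for _, _, o in dp.sample_patches(img, None, spec)]
        b = [o for _, _, o in dp.sample_patches(img, None, spec)]
        assert a == b

    def test_mask_patch_alignment(self):
        img = np.zeros((32, 32, 3), np.uint8)
        mask = np.zeros((32, 32), np.uint8)
        img[10, 20] = 255
        mask[10, 20] = 2
        spec = dp.PatchSpec(size_px=32, stride_px=32, count=1, seed=0)
        patch, mpatch, _ = dp.sample_patches(img, mask, spec)[0]
        assert (patch[..., 0] == 255).sum() == 1
        assert np.argwhere(mpatch == 2).tolist() == np.argwhere(
            patch[..., 0] == 255).tolist()

    def test_too_small_image(self):
        with pytest.raises(ValueError):
            dp.sample_patches(np.zeros((8, 8, 3)), None,
                              dp.PatchSpec(size_px=16, stride_px=16, count=1))


class TestSlidingWindow:
    def test_single_window_equals_direct_prediction(self, rng):
        img = rng.random((32, 32, 3))

        def fn(patch):
            p = patch[..., :3].copy()
            return p / p.sum(-1, keepdims=True)

        out = dp.sliding_window_predict(img, fn, size_px=32, stride_px=32)
        assert np.allclose(out, fn(img))

    def test_constant_prediction_stitches_constant(self, rng):
        img = rng.random((70, 90, 3))
        onehot = np.zeros((32, 32, 3))
        onehot[..., 1] = 1.0
        out = dp.sliding_window_predict(img, lambda p: onehot, size_px=32, stride_px=16)
        assert out.shape == (70, 90, 3)
        assert np.allclose(out[..., 1], 1.0)
        labels = dp.probabilities_to_labels(out)
        assert (labels == 1).all()

    def test_matches_brute_force_accumulation(self, rng):
        # oracle: enumerate every window, accumulate sums and coverage directly
        img = rng.random((50, 70, 3))

        def fn(patch):
            p = np.stack([patch[..., 0], patch[..., 1], patch[..., 2]], axis=-1)
            p = p + 0.1
            return p / p.sum(-1, keepdims=True)

        size, stride = 16, 8
        out = dp.sliding_window_predict(img, fn, size_px=size, stride_px=stride)

        rows = list(range(0, 50 - size + 1, stride))
        cols = list(range(0, 70 - size + 1, stride))
        if rows[-1] != 50 - size:
            rows.append(50 - size)
        if cols[-1] != 70 - size:
            cols.append(70 - size)
        acc = np.zeros((50, 70, 3))
        cov = np.zeros((50, 70))
        for r in rows:
            for c in cols:
                acc[r:r + size, c:c + size] += fn(img[r:r + size, c:c + size])
                cov[r:r + size, c:c + size] += 1
        assert cov.min() >= 1
        assert np.allclose(out, acc / cov[..., None], atol=1e-6)

    def test_small_image_reflect_padded(self, rng):
        img = rng.random((10, 12, 3))
        onehot = np.zeros((16, 16, 3))
        onehot[..., 2] = 1.0
        out = dp.sliding_window_predict(img, lambda p: onehot, size_px=16, stride_px=16)
        assert out.shape == (10, 12, 3)

    def test_probabilities_sum_to_one(self, rng):
        img = rng.random((40, 40, 3))

        def fn(patch):
            z = rng.random((16, 16, 3)) + 0.5
            return z / z.sum(-1, keepdims=True)

        out = dp.sliding_window_predict(img, fn, size_px=16, stride_px=8)
        assert np.allclose(out.sum(-1), 1.0, atol=1e-6)
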