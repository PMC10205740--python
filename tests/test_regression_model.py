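import numpy as np
import pytest

from epiderm import dataset_io as dio
from epiderm import regression_model as rm

TINY = dict(width_scale=0.1, epochs=2, steps_per_epoch=5, batch_size=4,
            learning_rate=0.01)


class TestBuild:
    def test_pretrained_without_weights_rejected(self):
        with pytest.raises(ValueError, match="pretrained"):
            rm.build_regressor(rm.RegressorConfig(pretrained=True))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            rm.RegressorConfig(backbone="resnet")
        with pytest.raises(ValueError):
            rm.RegressorConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            rm.RegressorConfig(loss="huber")

    def test_masker_config_invariants(self):
        with pytest.raises(ValueError):
            rm.MaskerConfig(encoder_widths=(64, 32))
        with pytest.raises(ValueError):
            rm.MaskerConfig(threshold=0.0)


class TestMaskImage:
    def test_all_ones_mask_is_identity(self, rng):
        img = rng.integers(0, 255, (8, 8, 3)).astype(np.uint8)
        assert np.array_equal(rm.mask_image(img, np.ones((8, 8))), img)

    def test_all_zeros_blacks_out(self, rng):
        img = rng.integers(1, 255, (8, 8, 3)).astype(np.uint8)
        assert rm.mask_image(img, np.zeros((8, 8))).sum() == 0

    def test_checkerboard(self, rng):
        img = rng.integers(1, 255, (8, 8, 3)).astype(np.uint8)
        board = np.indices((8, 8)).sum(0) % 2
        out = rm.mask_image(img, board)
        assert (out[board == 0] == 0).all()
        assert np.array_equal(out[board == 1], img[board == 1])

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            rm.mask_image(np.zeros((8, 8, 3), np.uint8), np.ones((4, 4)))


class TestTrainRegressor:
    def test_loss_decreases_on_scaled_run(self, ds_reg_small):
        ids = [r.sample_id for r in ds_reg_small.records]
        cfg = rm.RegressorConfig(width_scale=0.1, epochs=10, steps_per_epoch=5,
                                 batch_size=8, learning_rate=0.01, seed=0)
        _, history = rm.train_regressor(ds_reg_small, ids, "s_nuclei", cfg)
        assert history[-1] < history[0]

    def test_missing_target_rejected(self, ds_small):
        rec = dio.SampleRecord("noarea", ds_small.records[0].image_path,
                               "human_skin", "CPD", 0.5)
        manifest = dio.DatasetManifest(records=[rec])
        cfg = rm.RegressorConfig(**TINY)
        with pytest.raises(ValueError, match="lacks target"):
            rm.train_regressor(manifest, ["noarea"], "s_area", cfg)

    def test_empty_fold_rejected(self, ds_small):
        with pytest.raises(ValueError, match="empty"):
            rm.train_regressor(ds_small, [], "s_nuclei", rm.RegressorConfig(**TINY))

    def test_same_seed_same_loss_curve(self, ds_small):
        ids = [r.sample_id for r in ds_small.records[:6]]
        cfg = rm.RegressorConfig(seed=4, **TINY)
        _, h1 = rm.train_regressor(ds_small, ids, "s_nuclei", cfg)
        _, h2 = rm.train_regressor(ds_small, ids, "s_nuclei", cfg)
        assert h1 == h2


class TestPredictScore:
    def test_output_in_unit_interval_on_noise(self, rng):
        cfg = rm.RegressorConfig(width_scale=0.05, seed=0)
        model = rm.build_regressor(cfg)
        noise = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
        p = rm.predict_score(model, noise, cfg)
        assert 0.0 < p < 1.0

    def test_all_ones_mask_matches_plain_path(self, ds_small, rng):
        # masking with a full-support mask must not change the prediction
        cfg = rm.RegressorConfig(width_scale=0.05, seed=1)
        model = rm.build_regressor(cfg)
        image, _ = dio.load_sample(ds_small.records[0])
        plain = rm.predict_score(model, image, cfg)
        masked_input = rm.mask_image(image, np.ones(image.shape[:2]))
        masked = rm.predict_score(model, masked_input, cfg)
        assert plain == pytest.approx(masked)

    def test_true_mask_preserves_epidermis_support(self, ds_small):
        # masking with the ground-truth epidermis zeroes only background
        rec = next(r for r in ds_small.records if r.has_segmentation)
        image, mask = dio.load_sample(rec)
        out = rm.mask_image(image, mask > 0)
        assert np.array_equal(out[mask > 0], image[mask > 0])
        assert out[mask == 0].sum() == 0


class TestMasker:
    def test_trained_masker_recovers_epidermis(self, ds_medium):
        ids = [r.sample_id for r in ds_medium.records]
        train, test = ids[:20], ids[20:]
        mcfg = rm.MaskerConfig(encoder_widths=(16, 32, 64), epochs=10,
                               batches_per_epoch=10, batch_size=8,
                               learning_rate=0.01, seed=0)
        masker, history = rm.build_and_train_masker(ds_medium, train, mcfg)
        assert history[-1] < history[0]
        ious = []
        for sid in test:
            image, mask = dio.load_sample(ds_medium.by_id(sid))
            fg = rm.predict_epidermis(masker, image, mcfg)
            truth = mask > 0
            ious.append(np.logical_and(fg, truth).sum()
                        / np.logical_or(fg, truth).sum())
        assert float(np.mean(ious)) >= 0.6

    def test_masker_output_shape_and_range(self, ds_small, rng):
        mcfg = rm.MaskerConfig(encoder_widths=(4, 8), seed=0)
        masker = __import__("epiderm").nn.UNet(widths=(4, 8), out_channels=1, seed=0)
        image, _ = dio.load_sample(ds_small.records[0])
        fg = rm.predict_epidermis(masker, image, mcfg)
        assert fg.shape == image.shape[:2]
        assert fg.dtype == bool

    def test_threshold_idempotent(self, rng):
        prob = rng.random((16, 16))
        binary = (prob >= 0.5).astype(np.uint8)
        again = (binary >= 0.5).astype(np.uint8)
        assert np.array_equal(binary, again)

    def test_no_masked_samples_rejected(self, ds_small):
        with pytest.raises(ValueError, match="no masked"):
            rm.build_and_train_masker(ds_small, [], rm.MaskerConfig())
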