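"""Scalar damage-score regression, plain and epidermis-masked.

The regressor maps a 4x-downsampled RGB field of view straight to a score
in (0, 1): a VGG16-style backbone, concatenated global max- and
mean-pooling (1024 = 512 + 512 at full width), dropout, a 128-unit ReLU
layer, dropout and one sigmoid output neuron.  The masked variant first
zeroes every non-epidermis pixel using a separately trained binary U-Net
(encoder widths 32/64/128/256, per-pixel binary cross-entropy, Adamax),
forcing the score to be inferred from epidermis pixels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data_pipeline import (AugmentPolicy, PatchSpec, augment, downsample,
                            sample_patches, sliding_window_predict,
                            upsample_mask)
from .dataset_io import load_sample


@dataclass(frozen=True)
class RegressorConfig:
    backbone: str = "vgg16_style"
    pretrained: bool = False
    pretrained_weights: str | None = None
    width_scale: float = 1.0
    head_hidden: int = 128
    dropout_rate: float = 0.5
    downsample_factor: int = 4
    loss: str = "mse"
    learning_rate: float = 1e-3
    epochs: int = 50
    steps_per_epoch: int = 100
    batch_size: int = 32
    seed: int = 0
    augment: AugmentPolicy = field(default_factory=lambda: AugmentPolicy(
        flips=True, brightness_range=(0.75, 1.25), rotation_deg=(0.0, 0.0)))

    def __post_init__(self):
        if self.backbone != "vgg16_style":
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")


@dataclass(frozen=True)
class MaskerConfig:
    """Binary epidermis U-Net recipe (foreground = healthy + damaged)."""

    encoder_widths: tuple[int, ...] = (32, 64, 128, 256)
    epochs: int = 150
    batches_per_epoch: int = 50
    batch_size: int = 32
    patch_px: int = 256
    downsample_factor: int = 2
    learning_rate: float = 1e-3
    threshold: float = 0.5
    seed: int = 0
    augment: AugmentPolicy = field(default_factory=lambda: AugmentPolicy(
        flips=True, brightness_range=(0.75, 1.25), rotation_deg=(0.0, 0.0)))

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.encoder_widths, self.encoder_widths[1:])):
            raise ValueError("encoder_widths must be strictly increasing")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


def _to_input(image: np.ndarray) -> np.ndarray:
    return image.astype(np.float32) / 255.0 - 0.5


def build_regressor(config: RegressorConfig) -> nn.VGGRegressor:
    if config.pretrained and config.pretrained_weights is None:
        raise ValueError(
            "pretrained=True needs a pretrained_weights file; ImageNet weights "
            "are not bundled — train from scratch or supply a checkpoint")
    model = nn.VGGRegressor(width_scale=config.width_scale,
                            head_hidden=config.head_hidden,
                            dropout_rate=config.dropout_rate,
                            seed=config.seed)
    if config.pretrained_weights is not None:
        data = np.load(config.pretrained_weights)
        for i, p in enumerate(model.parameters()):
            p.w[...] = data[f"p{i}"]
    return model


def _target_of(record, target: str):
    if target == "s_nuclei":
        return record.s_nuclei
    if target == "s_area":
        return record.s_area
    raise ValueError(f"target must be 's_nuclei' or 's_area', got {target!r}")


def train_regressor(manifest, train_ids, target: str, config: RegressorConfig,
                    masker: nn.UNet | None = None,
                    masker_config: MaskerConfig | None = None):
    """Train the score regressor on one fold; returns (model, history).

    With ``masker`` given this is the masked-regression variant: every
    training image is epidermis-masked before downsampling-resolution
    training, exactly as at prediction time.
    """
    ids = list(train_ids) if train_ids is not None else [r.sample_id for r in manifest.records]
    if not ids:
        raise ValueError("empty training fold")
    images, targets = [], []
    for sid in ids:
        rec = manifest.by_id(sid)
        y = _target_of(rec, target)
        if y is None:
            raise ValueError(f"training sample {sid} lacks target {target}")
        image, _ = load_sample(rec, manifest.palette)
        small = downsample(image, config.downsample_factor, "image")
        if masker is not None:
            epi = predict_epidermis(masker, image, masker_config or MaskerConfig())
            epi_small = upsample_mask(epi.astype(np.uint8), small.shape[:2])
            small = mask_image(small, epi_small)
        images.append(small)
        targets.append(float(y))
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise ValueError(f"training images differ in shape: {sorted(shapes)}")
    targets = np.asarray(targets, dtype=np.float64)

    model = build_regressor(config)
    opt = nn.Adamax(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = []
    for _ in range(config.epochs):
        losses = []
        for _ in range(config.steps_per_epoch):
            idx = rng.integers(0, len(images), size=min(config.batch_size, len(images)))
            xb = []
            for i in idx:
                img, _ = augment(images[i], None, config.augment,
                                 np.random.default_rng(rng.integers(2 ** 31)))
                xb.append(_to_input(img))
            x = np.stack(xb)
            y = targets[idx]
            opt.zero_grad()
            logits = model.forward(x, train=True)
            loss, g = nn.sigmoid_regression_loss(logits, y, config.loss)
            model.backward(g)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def build_and_train_masker(manifest, train_ids, config: MaskerConfig):
    """Train the binary epidermis masker on masked samples of one fold.

    Foreground is epidermis (classes 1 and 2 collapsed); loss is per-pixel
    binary cross-entropy under Adamax.  Returns (model, history).
    """
    ids = list(train_ids) if train_ids is not None else [
        r.sample_id for r in manifest.records if r.has_segmentation]
    pairs = []
    for sid in ids:
        rec = manifest.by_id(sid)
        if not rec.has_segmentation:
            raise ValueError(f"training sample {sid} carries no mask")
        image, mask = load_sample(rec, manifest.palette)
        pairs.append((downsample(image, config.downsample_factor, "image"),
                      downsample((mask > 0).astype(np.uint8),
                                 config.downsample_factor, "mask")))
    if not pairs:
        raise ValueError("no masked samples in fold")

    model = nn.UNet(widths=config.encoder_widths, out_channels=1, seed=config.seed)
    opt = nn.Adamax(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    pool_side = 2 ** (len(config.encoder_widths) - 1)
    history = []
    for _ in range(config.epochs):
        losses = []
        for _ in range(config.batches_per_epoch):
            xb, yb = [], []
            for _ in range(config.batch_size):
                img, msk = pairs[rng.integers(len(pairs))]
                img, msk = augment(img, msk, config.augment,
                                   np.random.default_rng(rng.integers(2 ** 31)))
                limit = (min(img.shape[:2]) // pool_side) * pool_side
                size = min(config.patch_px, limit)
                spec = PatchSpec(size_px=size, stride_px=size, count=1,
                                 seed=int(rng.integers(2 ** 31)))
                patch, mpatch, _ = sample_patches(img, msk, spec)[0]
                xb.append(_to_input(patch))
                yb.append(mpatch.astype(np.float32)[..., None])
            opt.zero_grad()
            logits = model.forward(np.stack(xb), train=True)
            loss, g = nn.sigmoid_bce(logits, np.stack(yb))
            model.backward(g)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def predict_epidermis(masker: nn.UNet, image: np.ndarray,
                      config: MaskerConfig) -> np.ndarray:
    """Binary epidermis mask at the input image's resolution."""
    small = downsample(image, config.downsample_factor, "image")
    pool_side = 2 ** (len(config.encoder_widths) - 1)
    limit = (min(small.shape[:2]) // pool_side) * pool_side
    size = min(config.patch_px, max(limit, pool_side))
    prob = sliding_window_predict(
        _to_input(small), lambda patch: masker.predict_proba(patch[None])[0],
        size_px=size, stride_px=max(size // 2, 1))
    fg = (prob[..., 0] >= config.threshold).astype(np.uint8)
    return upsample_mask(fg, image.shape[:2]).astype(bool)


def mask_image(image: np.ndarray, epidermis_mask: np.ndarray) -> np.ndarray:
    """Zero all non-epidermis pixels; epidermis pixels pass unchanged."""
    epidermis_mask = np.asarray(epidermis_mask)
    if epidermis_mask.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {epidermis_mask.shape} != image shape {image.shape[:2]}")
    return image * (epidermis_mask > 0).astype(image.dtype)[..., None]


def predict_score(model: nn.VGGRegressor, image: np.ndarray,
                  config: RegressorConfig, masker: nn.UNet | None = None,
                  masker_config: MaskerConfig | None = None) -> float:
    """Predicted damage score in (0, 1) for one full-resolution image."""
    small = downsample(image, config.downsample_factor, "image")
    if masker is not None:
        epi = predict_epidermis(masker, image, masker_config or MaskerConfig())
        epi_small = upsample_mask(epi.astype(np.uint8), small.shape[:2])
        small = mask_image(small, epi_small)
    return float(model.predict(_to_input(small)[None])[0])
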