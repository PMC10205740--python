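"""Three-class damage segmentation (background / healthy / damaged epidermis).

A U-Net that pools three times, with base widths 16, 32 or 64 (channel
progression w, 2w, 4w and an 8w bottleneck), trained on randomly sampled
patches of 2x-downsampled images with flip / brightness / +-15 degree
rotation augmentation, Adamax and categorical cross-entropy.  Full-image
prediction runs a sliding window over the downsampled image, averages
overlapping probability maps, takes the per-pixel argmax and upsamples the
labels back to the original resolution; the area damage score S_area is
then an exact pixel tally on the predicted mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data_pipeline import (AugmentPolicy, PatchSpec, augment, downsample,
                            probabilities_to_labels, sample_patches,
                            sliding_window_predict, upsample_mask)
from .dataset_io import load_sample
from .scores import ScorePair, s_area_from_mask

ALLOWED_BASE_WIDTHS = (16, 32, 64)


@dataclass(frozen=True)
class UNetConfig:
    """Training recipe of the study; override fields for desk-scale runs."""

    base_width: int = 64
    pool_count: int = 3
    patch_px: int = 256
    downsample_factor: int = 2
    classes: int = 3
    epochs: int = 50
    steps_per_epoch: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    seed: int = 0
    allow_any_width: bool = False
    augment: AugmentPolicy = field(default_factory=lambda: AugmentPolicy(
        flips=True, brightness_range=(0.75, 1.25), rotation_deg=(-15.0, 15.0)))

    def __post_init__(self):
        if self.base_width not in ALLOWED_BASE_WIDTHS and not self.allow_any_width:
            raise ValueError(
                f"base_width must be one of {ALLOWED_BASE_WIDTHS} "
                "(set allow_any_width=True to override)")
        if self.patch_px % (2 ** self.pool_count):
            raise ValueError("patch_px must be divisible by 2**pool_count")

    @property
    def widths(self) -> tuple[int, ...]:
        w = self.base_width
        return tuple(w * 2 ** i for i in range(self.pool_count + 1))


def build_unet(config: UNetConfig) -> nn.UNet:
    return nn.UNet(widths=config.widths, in_channels=3,
                   out_channels=config.classes, seed=config.seed)


def _to_input(image: np.ndarray) -> np.ndarray:
    return image.astype(np.float32) / 255.0 - 0.5


def _effective_patch(config: UNetConfig, shape) -> int:
    side = 2 ** config.pool_count
    limit = (min(shape[:2]) // side) * side
    if limit < side:
        raise ValueError(f"image {shape[:2]} too small for {config.pool_count} poolings")
    return min(config.patch_px, limit)


def _load_training_arrays(manifest, train_ids, config: UNetConfig):
    ids = list(train_ids) if train_ids is not None else [
        r.sample_id for r in manifest.records if r.has_segmentation]
    pairs = []
    for sid in ids:
        rec = manifest.by_id(sid)
        if not rec.has_segmentation:
            raise ValueError(f"training sample {sid} carries no mask")
        image, mask = load_sample(rec, manifest.palette)
        pairs.append((downsample(image, config.downsample_factor, "image"),
                      downsample(mask, config.downsample_factor, "mask")))
    if not pairs:
        raise ValueError("no masked training samples in fold")
    return pairs


def _train_one(pairs, config: UNetConfig, seed: int):
    model = nn.UNet(widths=config.widths, out_channels=config.classes, seed=seed)
    opt = nn.Adamax(model.parameters(), lr=config.learning_rate,
                    beta1=config.beta1, beta2=config.beta2, eps=config.epsilon)
    rng = np.random.default_rng(seed)
    eye = np.eye(config.classes, dtype=np.float32)
    history = []
    for _ in range(config.epochs):
        losses = []
        for _ in range(config.steps_per_epoch):
            xb, yb = [], []
            for _ in range(config.batch_size):
                img, msk = pairs[rng.integers(len(pairs))]
                img, msk = augment(img, msk, config.augment,
                                   np.random.default_rng(rng.integers(2 ** 31)))
                size = _effective_patch(config, img.shape)
                spec = PatchSpec(size_px=size, stride_px=size, count=1,
                                 seed=int(rng.integers(2 ** 31)))
                patch, mpatch, _ = sample_patches(img, msk, spec)[0]
                xb.append(_to_input(patch))
                yb.append(eye[mpatch])
            x = np.stack(xb)
            y = np.stack(yb)
            opt.zero_grad()
            logits = model.forward(x, train=True)
            loss, g = nn.softmax_cross_entropy(logits, y)
            model.backward(g)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def train_segmenter(manifest, train_ids, config: UNetConfig, repeats: int = 5):
    """Train ``repeats`` independent models on one fold's training samples.

    The study trains every width variant five times per fold; repeat ``r``
    uses seed ``config.seed + r`` so the repeat list is reproducible from
    the base seed alone.  Returns (models, histories).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    pairs = _load_training_arrays(manifest, train_ids, config)
    models, histories = [], []
    for r in range(repeats):
        model, hist = _train_one(pairs, config, seed=config.seed + r)
        models.append(model)
        histories.append(hist)
    return models, histories


def repeat_seeds(config: UNetConfig, repeats: int = 5) -> list[int]:
    return [config.seed + r for r in range(repeats)]


def predict_mask(model: nn.UNet, image: np.ndarray, config: UNetConfig,
                 stride_px: int | None = None):
    """Full-image prediction: downsample, slide, argmax, upsample labels.

    Returns (label mask at input resolution, class-probability map at input
    resolution).
    """
    small = downsample(image, config.downsample_factor, "image")
    size = _effective_patch(config, small.shape)
    stride = stride_px if stride_px is not None else max(size // 2, 1)
    stride = min(stride, size)
    prob = sliding_window_predict(
        _to_input(small), lambda patch: model.predict_proba(patch[None])[0],
        size_px=size, stride_px=stride)
    labels_small = probabilities_to_labels(prob)
    labels = upsample_mask(labels_small, image.shape[:2])
    prob_full = np.stack([upsample_mask(prob[..., c], image.shape[:2])
                          for c in range(prob.shape[-1])], axis=-1)
    return labels, prob_full


def score_from_prediction(model: nn.UNet, image: np.ndarray,
                          config: UNetConfig) -> ScorePair:
    """S_area from the predicted mask; raises UndefinedScoreError when the
    model predicts no epidermis at all (the epidermis-detection failure
    mode must surface, not silently score 0)."""
    labels, _ = predict_mask(model, image, config)
    pair, _ = s_area_from_mask(labels)
    return pair
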