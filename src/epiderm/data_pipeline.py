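"""Image transforms shared by the segmentation and regression models.

Downsampling (bilinear for images, nearest for label masks), the basic
augmentation policy (axis flips, multiplicative brightness in [0.75, 1.25],
small rotations), random patch sampling, and sliding-window prediction with
probability-averaged stitching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize, rotate

# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def downsample(arr: np.ndarray, factor: int, kind: str = "image") -> np.ndarray:
    """Downsample by an integer factor; output dims are ceil(input / factor).

    Images are resized bilinearly (anti-aliased, dtype preserved); masks use
    nearest-neighbour so the label set is preserved exactly.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if kind not in ("image", "mask"):
        raise ValueError(f"kind must be 'image' or 'mask', got {kind!r}")
    if factor == 1:
        return arr.copy()
    h = -(-arr.shape[0] // factor)
    w = -(-arr.shape[1] // factor)
    shape = (h, w) + arr.shape[2:]
    if kind == "image":
        out = resize(arr.astype(np.float64), shape, order=1, anti_aliasing=True,
                     mode="reflect", preserve_range=True)
        if np.issubdtype(arr.dtype, np.integer):
            out = np.rint(np.clip(out, 0, 255))
        return out.astype(arr.dtype)
    out = resize(arr, shape, order=0, anti_aliasing=False, mode="edge",
                 preserve_range=True)
    return out.astype(arr.dtype)


def upsample_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsampling of a label mask to exact output dims."""
    out = resize(mask, shape, order=0, anti_aliasing=False, mode="edge",
                 preserve_range=True)
    return out.astype(mask.dtype)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentPolicy:
    """Knobs of the training-time augmentation; the defaults are the study's."""

    flips: bool = True
    brightness_range: tuple[float, float] = (0.75, 1.25)
    rotation_deg: tuple[float, float] = (0.0, 0.0)

    @property
    def neutral(self) -> bool:
        return (not self.flips and self.brightness_range == (1.0, 1.0)
                and self.rotation_deg == (0.0, 0.0))


def augment(image: np.ndarray, mask: np.ndarray | None, policy: AugmentPolicy,
            rng: np.random.Generator | int):
    """Apply one random draw of the augmentation policy.

    Geometric transforms (flips, rotation) are applied identically to image
    and mask; brightness is a multiplicative factor on the image only,
    clipped to [0, 255].  Deterministic for a fixed seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if mask is not None and mask.shape[:2] != image.shape[:2]:
        raise ValueError(f"mask shape {mask.shape[:2]} != image shape {image.shape[:2]}")
    img = image
    if policy.flips:
        if rng.random() < 0.5:
            img = img[::-1]
            mask = mask[::-1] if mask is not None else None
        if rng.random() < 0.5:
            img = img[:, ::-1]
            mask = mask[:, ::-1] if mask is not None else None
    lo, hi = policy.rotation_deg
    angle = float(rng.uniform(lo, hi))
    if angle != 0.0:
        img = rotate(img.astype(np.float64), angle, order=1, mode="reflect",
                     preserve_range=True)
        if mask is not None:
            mask = rotate(mask, angle, order=0, mode="reflect",
                          preserve_range=True).astype(mask.dtype)
    blo, bhi = policy.brightness_range
    factor = float(rng.uniform(blo, bhi))
    if factor != 1.0 or angle != 0.0:
        img = np.clip(np.asarray(img, dtype=np.float64) * factor, 0, 255)
        if np.issubdtype(image.dtype, np.integer):
            img = np.rint(img)
    img = np.ascontiguousarray(img).astype(image.dtype)
    mask = np.ascontiguousarray(mask) if mask is not None else None
    return img, mask


# ---------------------------------------------------------------------------
# patch sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchSpec:
    size_px: int = 256
    stride_px: int = 128
    count: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.stride_px <= self.size_px:
            raise ValueError("need 0 < stride_px <= size_px")
        if self.count < 1:
            raise ValueError("count must be >= 1")


def sample_patches(image: np.ndarray, mask: np.ndarray | None, spec: PatchSpec):
    """Draw ``spec.count`` fully in-bounds patches at uniform-random origins.

    Returns a list of (patch, mask_patch-or-None, (row, col)) tuples.
    """
    H, W = image.shape[:2]
    s = spec.size_px
    if H < s or W < s:
        raise ValueError(f"image {H}x{W} smaller than patch size {s}")
    rng = np.random.default_rng(spec.seed)
    rows = rng.integers(0, H - s + 1, size=spec.count)
    cols = rng.integers(0, W - s + 1, size=spec.count)
    out = []
    for r, c in zip(rows, cols):
        mp = mask[r:r + s, c:c + s] if mask is not None else None
        out.append((image[r:r + s, c:c + s], mp, (int(r), int(c))))
    return out


# ---------------------------------------------------------------------------
# sliding-window inference
# ---------------------------------------------------------------------------


def _grid(extent: int, size: int, stride: int) -> list[int]:
    """Window origins covering [0, extent): a stride grid with the last
    origin snapped to the edge so no pixel is left uncovered."""
    if extent <= size:
        return [0]
    origins = list(range(0, extent - size + 1, stride))
    if origins[-1] != extent - size:
        origins.append(extent - size)
    return origins


def sliding_window_predict(image: np.ndarray, per_patch_fn, size_px: int,
                           stride_px: int) -> np.ndarray:
    """Stitch per-window class-probability maps into a full-image map.

    Overlapping windows are averaged per pixel.  Images smaller than the
    window are reflect-padded up to window size and the result cropped
    back.  The returned map has shape (H, W, C) with per-pixel
    probabilities summing to 1 whenever ``per_patch_fn`` returns proper
    probability maps.
    """
    if stride_px > size_px:
        raise ValueError("stride must not exceed window size")
    H, W = image.shape[:2]
    pad_h = max(0, size_px - H)
    pad_w = max(0, size_px - W)
    if pad_h or pad_w:
        image = np.pad(image, ((0, pad_h), (0, pad_w)) + ((0, 0),) * (image.ndim - 2),
                       mode="reflect")
    Hp, Wp = image.shape[:2]
    acc = None
    cover = np.zeros((Hp, Wp), dtype=np.float64)
    for r in _grid(Hp, size_px, stride_px):
        for c in _grid(Wp, size_px, stride_px):
            prob = np.asarray(per_patch_fn(image[r:r + size_px, c:c + size_px]),
                              dtype=np.float64)
            if prob.shape[:2] != (size_px, size_px):
                raise ValueError("per_patch_fn must return a size_px x size_px map")
            if acc is None:
                acc = np.zeros((Hp, Wp, prob.shape[-1]), dtype=np.float64)
            acc[r:r + size_px, c:c + size_px] += prob
            cover[r:r + size_px, c:c + size_px] += 1.0
    assert cover.min() >= 1.0
    acc /= cover[..., None]
    return acc[:H, :W]


def probabilities_to_labels(prob: np.ndarray) -> np.ndarray:
    """Argmax with ties broken toward the lower class index."""
    return prob.argmax(axis=-1).astype(np.uint8)
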