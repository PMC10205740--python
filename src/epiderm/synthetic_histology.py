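"""Synthetic stained-epidermis generator with exact ground truth.

Emulates the immunohistochemistry fields of view the damage pipeline is
built for: an undulating epidermis band touching the top image edge over a
darker dermis, keratinocyte nuclei confined to the band, red chromogen on
DNA-damaged nuclei (and a diffuse chromogen tint over damaged regions, as
immunostains deposit beyond the nuclear outline), plus a pathologist model
whose annotation noise grows with spatial damage heterogeneity.

Damage placement: a Gaussian-smoothed white-noise field is thresholded at
the quantile that makes the damaged share of the band equal the target
fraction; the smoothing length scale is the single heterogeneity knob
(0 = fine-grained speckle = homogeneous damage, 1 = few large patches).
Every class-2 pixel is inside the band by construction, and the recorded
true scores are exact pixel/nucleus tallies.

The renderer makes no claim of histological realism beyond what a
segmentation model needs to learn the three classes; the low-contrast knob
compresses all colours toward the slide background to reproduce the regime
where epidermis detection fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse

from . import dataset_io
from .dataset_io import DatasetManifest, SampleRecord
from .scores import ScorePair

# rendering palette (RGB, 8-bit)
SLIDE_BG = (247.0, 240.0, 243.0)
BAND_TISSUE = (229.0, 186.0, 205.0)
DERMIS = (213.0, 168.0, 189.0)
CHROMOGEN = (182.0, 92.0, 80.0)      # diffuse stain over damaged regions
NUCLEUS_HEALTHY = (88.0, 70.0, 150.0)
NUCLEUS_DAMAGED = (163.0, 38.0, 46.0)
CHROMOGEN_ALPHA = 0.35


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic slide; defaults give a 256x256 desk-scale field.

    The full-slide preset (1040x1384 px at 0.645 um/px) matches the
    acquisition geometry of the real dataset.
    """

    height_px: int = 256
    width_px: int = 256
    resolution_um_per_px: float = 0.645
    band_thickness_um: tuple[float, float] = (45.0, 70.0)
    undulation_amplitude_um: float = 12.0
    undulation_period_um: float = 60.0
    nuclei_density_per_um2: float = 0.008
    target_damage_fraction: float = 0.3
    heterogeneity: float = 0.5
    contrast: float = 1.0
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.target_damage_fraction <= 1.0:
            raise GeneratorConfigError("target_damage_fraction must be in [0, 1]")
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise GeneratorConfigError("heterogeneity must be in [0, 1]")
        if not 0.0 < self.contrast <= 1.0:
            raise GeneratorConfigError("contrast must be in (0, 1]")
        if self.nuclei_density_per_um2 <= 0 or self.resolution_um_per_px <= 0:
            raise GeneratorConfigError("densities and sizes must be > 0")
        lo, hi = self.band_thickness_um
        if not 0 < lo <= hi:
            raise GeneratorConfigError("band_thickness_um must be a positive (lo, hi) range")
        if lo / self.resolution_um_per_px < 2.0:
            raise GeneratorConfigError(
                "band thinner than 2 px at the declared resolution")


FULL_SLIDE = GeneratorConfig(height_px=1040, width_px=1384)


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray
    mask: np.ndarray
    nuclei: list[tuple[int, int, bool]]  # (x_px, y_px, damaged)
    true_scores: ScorePair
    heterogeneity_value: float


def generate_sample(config: GeneratorConfig) -> SyntheticSample:
    """Render one synthetic field of view; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    H, W = config.height_px, config.width_px
    res = config.resolution_um_per_px

    # --- epidermis band geometry -----------------------------------------
    thickness_px = rng.uniform(*config.band_thickness_um) / res
    amp_px = config.undulation_amplitude_um / res
    period_px = max(config.undulation_period_um / res, 4.0)
    x = np.arange(W)
    phase_top, phase_bot = rng.uniform(0, 2 * math.pi, size=2)
    y_top = 0.2 * amp_px * (1.0 + np.sin(2 * math.pi * x / (1.37 * period_px) + phase_top))
    y_top -= y_top.min()  # the band touches the top image edge
    y_bot = y_top + thickness_px + amp_px * np.sin(2 * math.pi * x / period_px + phase_bot)
    y_bot = np.clip(y_bot, None, H - 1)
    if float(np.min(y_bot - y_top)) < 2.0:
        raise GeneratorConfigError("band thinner than 2 px after undulation")
    rows = np.arange(H)[:, None]
    band = (rows >= y_top[None, :]) & (rows < y_bot[None, :])

    # --- damage field ------------------------------------------------------
    sigma = 1.0 + config.heterogeneity * (min(H, W) / 4.0)
    field_ = gaussian_filter(rng.standard_normal((H, W)), sigma)
    f = config.target_damage_fraction
    if f <= 0.0:
        damaged = np.zeros_like(band)
    elif f >= 1.0:
        damaged = band.copy()
    else:
        tau = np.quantile(field_[band], 1.0 - f)
        damaged = band & (field_ >= tau)

    mask = np.zeros((H, W), dtype=np.uint8)
    mask[band] = 1
    mask[damaged] = 2

    # --- nuclei -------------------------------------------------------------
    band_idx = np.flatnonzero(band)
    band_area_um2 = band_idx.size * res * res
    n_nuclei = max(1, int(rng.poisson(config.nuclei_density_per_um2 * band_area_um2)))
    n_nuclei = min(n_nuclei, band_idx.size)
    centers = rng.choice(band_idx, size=n_nuclei, replace=False)
    cy, cx = np.unravel_index(centers, (H, W))
    dmg_flags = damaged[cy, cx]
    nuclei = [(int(xx), int(yy), bool(dd)) for xx, yy, dd in zip(cx, cy, dmg_flags)]

    s_nuclei = float(dmg_flags.sum()) / n_nuclei
    a_dmg = int(damaged.sum())
    a_epi = int(band.sum())
    s_area = a_dmg / a_epi

    # --- rendering ----------------------------------------------------------
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = SLIDE_BG
    below = rows >= y_bot[None, :]
    img[below] = DERMIS
    img[band] = BAND_TISSUE
    img[damaged] = ((1 - CHROMOGEN_ALPHA) * np.asarray(BAND_TISSUE)
                    + CHROMOGEN_ALPHA * np.asarray(CHROMOGEN))
    # low-frequency mottle shared across channels
    mottle = gaussian_filter(rng.standard_normal((H, W)), 12.0)
    img += 40.0 * mottle[..., None]
    # nuclei as filled ellipses, 4-8 um diameter
    radii_um = rng.uniform(2.0, 4.0, size=(n_nuclei, 2))
    angles = rng.uniform(0, math.pi, size=n_nuclei)
    jitter = rng.normal(0, 6.0, size=(n_nuclei, 3))
    for i in range(n_nuclei):
        ry, rx_ = radii_um[i] / res
        rr, cc = ellipse(cy[i], cx[i], ry, rx_, shape=(H, W), rotation=angles[i])
        base = NUCLEUS_DAMAGED if dmg_flags[i] else NUCLEUS_HEALTHY
        img[rr, cc] = np.clip(np.asarray(base) + jitter[i], 0, 255)
    img += rng.normal(0.0, config.noise_sigma, size=img.shape)
    img = np.asarray(SLIDE_BG) + config.contrast * (img - np.asarray(SLIDE_BG))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return SyntheticSample(
        image=img,
        mask=mask,
        nuclei=nuclei,
        true_scores=ScorePair(s_nuclei=s_nuclei, s_area=s_area),
        heterogeneity_value=config.heterogeneity,
    )


# ---------------------------------------------------------------------------
# heterogeneity index
# ---------------------------------------------------------------------------


def heterogeneity_index(mask: np.ndarray, tile_px: int = 32) -> float:
    """Spatial unevenness of damage: sd of per-tile damage fractions / 0.5.

    Tiles without epidermis are ignored; the remaining tiles enter the
    standard deviation weighted by their epidermis pixel count, so slivers
    of band at a tile border do not dominate the estimate.  The value is
    clipped to [0, 1]; 0.5 is the largest attainable sd of a [0, 1]-valued
    quantity.
    """
    if tile_px < 8:
        raise ValueError("tile_px must be >= 8")
    mask = np.asarray(mask)
    if not (mask > 0).any():
        raise ValueError("mask contains no epidermis")
    H, W = mask.shape
    fracs, weights = [], []
    for r in range(0, H, tile_px):
        for c in range(0, W, tile_px):
            tile = mask[r:r + tile_px, c:c + tile_px]
            epi = (tile > 0).sum()
            if epi:
                fracs.append((tile == 2).sum() / epi)
                weights.append(epi)
    fracs = np.asarray(fracs)
    weights = np.asarray(weights, dtype=float)
    mean = np.average(fracs, weights=weights)
    sd = np.sqrt(np.average((fracs - mean) ** 2, weights=weights))
    return float(np.clip(sd / 0.5, 0.0, 1.0))


# ---------------------------------------------------------------------------
# annotator model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotatorConfig:
    """Truncated-Gaussian pathologist: noise sd grows linearly with heterogeneity.

    The default coupling is calibrated (see :func:`calibrate_coupling`) so
    that two independent annotators disagree with MAE ~ 0.2 on fully
    heterogeneous samples — the regime reported for pathologist pairs on
    critical samples.
    """

    base_noise_sd: float = 0.05
    heterogeneity_coupling: float = 0.14
    seed: int = 0

    def __post_init__(self):
        if self.base_noise_sd < 0 or self.heterogeneity_coupling < 0:
            raise ValueError("noise parameters must be >= 0")

    def noise_sd(self, heterogeneity_value: float) -> float:
        return self.base_noise_sd + self.heterogeneity_coupling * heterogeneity_value


def simulate_annotator(true_s_nuclei: float, heterogeneity_value: float,
                       config: AnnotatorConfig,
                       rng: np.random.Generator | None = None) -> float:
    """One noisy annotation of a true score, truncated to [0, 1]."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sd = config.noise_sd(heterogeneity_value)
    value = true_s_nuclei + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    return float(np.clip(value, 0.0, 1.0))


def annotator_pair_mae(config: AnnotatorConfig, heterogeneity_value: float = 1.0,
                       n_draws: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo MAE between two independent annotators of the same samples."""
    rng = np.random.default_rng(seed)
    truth = rng.uniform(0.1, 0.9, size=n_draws)
    sd = config.noise_sd(heterogeneity_value)
    a = np.clip(truth + rng.normal(0, sd, n_draws), 0, 1)
    b = np.clip(truth + rng.normal(0, sd, n_draws), 0, 1)
    return float(np.mean(np.abs(a - b)))


def calibrate_coupling(target_mae: float = 0.2, base_noise_sd: float = 0.05,
                       n_draws: int = 2000, seed: int = 0) -> float:
    """Coupling value at which two annotators reach ``target_mae`` at heterogeneity 1.

    Pair MAE is monotone in the coupling, so a bisection on [0, 1] against
    the Monte-Carlo estimate suffices.
    """
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        cfg = AnnotatorConfig(base_noise_sd=base_noise_sd, heterogeneity_coupling=mid)
        if annotator_pair_mae(cfg, 1.0, n_draws, seed) < target_mae:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

#: marginal composition of the real dataset (fractions of n = 804)
DEFAULT_STRATA: dict = {
    "tissue": {"human_skin": 487 / 804, "human_skin_model": 269 / 804,
               "porcine_skin": 48 / 804},
    "staining": {"CPD": 415 / 804, "64PP": 317 / 804, "MAA": 36 / 804, "MAC": 36 / 804},
    "segmentation_share": 202 / 804,
}


def _largest_remainder(n: int, probs: dict) -> dict:
    """Integer counts summing to n whose proportions best match ``probs``."""
    keys = list(probs)
    raw = np.array([probs[k] for k in keys], dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def draw_strata(n: int, strata: dict, seed: int) -> list[tuple[str, str, bool]]:
    """Per-sample (tissue, staining, has_segmentation) assignments.

    Each attribute's counts follow its marginal by largest remainder, then
    the three lists are independently shuffled and zipped.
    """
    total = sum(strata["tissue"].values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError("tissue probabilities must sum to 1")
    if not math.isclose(sum(strata["staining"].values()), 1.0, abs_tol=1e-9):
        raise ValueError("staining probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    tissues = [t for t, c in _largest_remainder(n, strata["tissue"]).items() for _ in range(c)]
    stains = [s for s, c in _largest_remainder(n, strata["staining"]).items() for _ in range(c)]
    n_seg = int(round(n * strata["segmentation_share"]))
    segs = [True] * n_seg + [False] * (n - n_seg)
    for lst in (tissues, stains, segs):
        rng.shuffle(lst)
    return list(zip(tissues, stains, segs))


def _sample_damage_fraction(rng: np.random.Generator) -> float:
    """Mixture covering [0, 1]: near-zero, mid-range beta, and near-one modes."""
    u = rng.random()
    if u < 0.15:
        return float(rng.uniform(0.0, 0.03))
    if u < 0.85:
        return float(rng.beta(1.5, 2.0))
    return float(rng.uniform(0.85, 1.0))


def generate_dataset(n: int, out_dir: str | Path, *, strata: dict | None = None,
                     config_template: GeneratorConfig | None = None,
                     seed: int = 0,
                     annotator: AnnotatorConfig | None = None) -> DatasetManifest:
    """Write an n-sample synthetic dataset in the standard layout.

    Per-sample damage fractions are drawn from a mixture covering [0, 1]
    and heterogeneity uniformly from [0, 1].  When ``annotator`` is given,
    the manifest's s_nuclei column carries that noisy annotation instead of
    the exact nucleus tally (emulating a pathologist-labelled manifest);
    the exact s_area of masked samples is always recorded.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    strata = strata if strata is not None else DEFAULT_STRATA
    template = config_template if config_template is not None else GeneratorConfig()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    assignments = draw_strata(n, strata, seed)
    master = np.random.default_rng(seed)
    ann_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1)[0])
    records = []
    from PIL import Image

    for i, (tissue, staining, has_seg) in enumerate(assignments):
        sid = f"s{i:04d}"
        sample_seed = int(master.integers(0, 2 ** 31 - 1))
        cfg = replace(template,
                      target_damage_fraction=_sample_damage_fraction(master),
                      heterogeneity=float(master.random()),
                      seed=sample_seed)
        sample = generate_sample(cfg)
        img_rel = f"images/{sid}.png"
        Image.fromarray(sample.image).save(out_dir / img_rel)
        mask_rel = None
        s_area = None
        if has_seg:
            mask_rel = f"masks/{sid}.png"
            dataset_io.write_mask_png(sample.mask, out_dir / mask_rel)
            s_area = sample.true_scores.s_area
        s_nuc = sample.true_scores.s_nuclei
        if annotator is not None:
            s_nuc = simulate_annotator(s_nuc, sample.heterogeneity_value,
                                       annotator, rng=ann_rng)
        records.append(SampleRecord(
            sample_id=sid,
            image_path=out_dir / img_rel,
            tissue=tissue,
            staining=staining,
            s_nuclei=s_nuc,
            mask_path=(out_dir / mask_rel) if mask_rel else None,
            s_area=s_area,
        ))

    manifest = DatasetManifest(
        records=records,
        resolution_um_per_px=template.resolution_um_per_px,
        image_height_px=template.height_px,
        image_width_px=template.width_px,
    )
    dataset_io.write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
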