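"""Dataset layout: RGB images, 3-class label masks, and a CSV manifest.

Layout on disk::

    <root>/manifest.csv      one row per sample
    <root>/dataset.yaml      optional sidecar: resolution, image dims,
                             exclusion list, mask palette override
    <root>/images/<id>.png   RGB 8-bit
    <root>/masks/<id>.png    paletted or single-channel PNG, classes {0,1,2}

Manifest columns: ``sample_id, image, tissue, staining, s_nuclei`` and the
optional ``mask`` and ``s_area``.  Paths are relative to the manifest's
directory.  Mask class encoding is 0 = background, 1 = healthy epidermis,
2 = damaged epidermis; RGB-encoded masks are translated through a
colour-triplet table (default black/green/red, overridable in the sidecar).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

TISSUES = ("human_skin", "human_skin_model", "porcine_skin")
STAININGS = ("CPD", "64PP", "MAA", "MAC")

#: default mask palette: class index -> RGB triplet (background, healthy, damaged)
MASK_PALETTE: dict[int, tuple[int, int, int]] = {
    0: (0, 0, 0),
    1: (0, 170, 0),
    2: (220, 30, 30),
}

DEFAULT_RESOLUTION_UM_PER_PX = 0.645

REQUIRED_COLUMNS = ("sample_id", "image", "tissue", "staining", "s_nuclei")


class ManifestSchemaError(ValueError):
    """The manifest table is missing a required column."""


class ManifestValidationError(ValueError):
    """The manifest content violates an invariant (duplicate id, bad range...)."""


@dataclass
class SampleRecord:
    sample_id: str
    image_path: Path
    tissue: str
    staining: str
    s_nuclei: float
    mask_path: Path | None = None
    s_area: float | None = None

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ManifestValidationError(
                f"{self.sample_id}: unknown tissue {self.tissue!r} (expected one of {TISSUES})")
        if self.staining not in STAININGS:
            raise ManifestValidationError(
                f"{self.sample_id}: unknown staining {self.staining!r}")
        if not 0.0 <= self.s_nuclei <= 1.0:
            raise ManifestValidationError(
                f"{self.sample_id}: s_nuclei={self.s_nuclei} outside [0, 1]")
        if self.s_area is not None and not 0.0 <= self.s_area <= 1.0:
            raise ManifestValidationError(
                f"{self.sample_id}: s_area={self.s_area} outside [0, 1]")

    @property
    def has_segmentation(self) -> bool:
        return self.mask_path is not None


@dataclass
class DatasetManifest:
    records: list[SampleRecord]
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    image_height_px: int = 0
    image_width_px: int = 0
    palette: dict[int, tuple[int, int, int]] = field(default_factory=lambda: dict(MASK_PALETTE))

    def __post_init__(self):
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestValidationError(f"duplicate sample_id(s): {dup}")

    def __len__(self):
        return len(self.records)

    def by_id(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)


@dataclass
class ValidationReport:
    n: int
    per_tissue: dict[str, int]
    per_staining: dict[str, int]
    n_with_segmentation: int
    unreadable: list[str]


def _read_sidecar(manifest_path: Path) -> dict:
    sidecar = manifest_path.with_name("dataset.yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read and validate a CSV manifest (plus its optional YAML sidecar)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestSchemaError(f"manifest {path} missing required column(s): {missing}")
    meta = _read_sidecar(path)
    exclude = set(meta.get("exclude_ids") or [])
    root = path.parent
    records = []
    for row in df.itertuples(index=False):
        if row.sample_id in exclude:
            continue
        mask = getattr(row, "mask", None)
        mask_path = root / str(mask) if isinstance(mask, str) and mask else None
        s_area = getattr(row, "s_area", None)
        s_area = float(s_area) if s_area is not None and np.isfinite(s_area) else None
        records.append(SampleRecord(
            sample_id=str(row.sample_id),
            image_path=root / str(row.image),
            tissue=str(row.tissue),
            staining=str(row.staining),
            s_nuclei=float(row.s_nuclei),
            mask_path=mask_path,
            s_area=s_area,
        ))
    height = int(meta.get("image_height_px", 0))
    width = int(meta.get("image_width_px", 0))
    if (not height or not width) and records:
        for rec in records:
            try:
                with Image.open(rec.image_path) as im:
                    width, height = im.size
                break
            except OSError:
                continue
    palette = dict(MASK_PALETTE)
    for k, v in (meta.get("palette") or {}).items():
        palette[int(k)] = tuple(int(c) for c in v)
    return DatasetManifest(
        records=records,
        resolution_um_per_px=float(meta.get("resolution_um_per_px",
                                            DEFAULT_RESOLUTION_UM_PER_PX)),
        image_height_px=height,
        image_width_px=width,
        palette=palette,
    )


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write the CSV manifest and its YAML sidecar next to it."""
    path = Path(path)
    root = path.parent

    def _ref(p: Path | None) -> str:
        # paths inside the dataset root stay relative; others go absolute
        if p is None:
            return ""
        try:
            return p.relative_to(root).as_posix()
        except ValueError:
            return p.resolve().as_posix()

    rows = []
    for r in manifest.records:
        rows.append({
            "sample_id": r.sample_id,
            "image": _ref(r.image_path),
            "tissue": r.tissue,
            "staining": r.staining,
            "s_nuclei": r.s_nuclei,
            "mask": _ref(r.mask_path),
            "s_area": "" if r.s_area is None else r.s_area,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    with open(path.with_name("dataset.yaml"), "w") as fh:
        yaml.safe_dump({
            "resolution_um_per_px": manifest.resolution_um_per_px,
            "image_height_px": manifest.image_height_px,
            "image_width_px": manifest.image_width_px,
            "palette": {int(k): list(v) for k, v in manifest.palette.items()},
            "exclude_ids": [],
        }, fh, sort_keys=True)


def write_mask_png(mask: np.ndarray, path: str | Path,
                   palette: dict[int, tuple[int, int, int]] = MASK_PALETTE) -> None:
    """Write a {0,1,2} label mask as an 8-bit paletted PNG."""
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    flat = [0] * 768
    for idx, rgb in palette.items():
        flat[3 * idx:3 * idx + 3] = list(rgb)
    im.putpalette(flat)
    im.save(path)


def _decode_mask(arr: np.ndarray, palette: dict[int, tuple[int, int, int]]) -> np.ndarray:
    if arr.ndim == 2:
        classes = arr
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        classes = np.full(arr.shape[:2], 255, dtype=np.uint8)
        for idx, rgb in palette.items():
            classes[np.all(arr[..., :3] == np.asarray(rgb, dtype=arr.dtype), axis=-1)] = idx
        if (classes == 255).any():
            bad = arr[..., :3][classes == 255][0]
            raise ValueError(f"unknown mask colour {tuple(int(c) for c in bad)}")
    else:
        raise ValueError(f"unsupported mask array shape {arr.shape}")
    bad_vals = np.setdiff1d(np.unique(classes), list(palette))
    if bad_vals.size:
        raise ValueError(f"unknown mask value {int(bad_vals[0])}")
    return classes.astype(np.uint8)


def load_sample(record: SampleRecord,
                palette: dict[int, tuple[int, int, int]] = MASK_PALETTE):
    """Load (image, mask-or-None) for one record; masks are remapped to {0,1,2}."""
    with Image.open(record.image_path) as im:
        image = np.asarray(im.convert("RGB"), dtype=np.uint8)
    mask = None
    if record.mask_path is not None:
        with Image.open(record.mask_path) as im:
            if im.mode == "P":
                mask_arr = np.asarray(im)
            else:
                mask_arr = np.asarray(im)
        mask = _decode_mask(mask_arr, palette)
        if mask.shape != image.shape[:2]:
            raise ValueError(
                f"{record.sample_id}: mask shape {mask.shape} != image shape {image.shape[:2]}")
    return image, mask


def validate_dataset(manifest: DatasetManifest) -> ValidationReport:
    """Stratum counts and readability check; failures are reported, not raised."""
    per_tissue = {t: 0 for t in TISSUES}
    per_staining = {s: 0 for s in STAININGS}
    unreadable: list[str] = []
    n_seg = 0
    for rec in manifest.records:
        per_tissue[rec.tissue] += 1
        per_staining[rec.staining] += 1
        if rec.has_segmentation:
            n_seg += 1
        for p in (rec.image_path, rec.mask_path):
            if p is not None and not Path(p).exists():
                unreadable.append(str(p))
    return ValidationReport(
        n=len(manifest.records),
        per_tissue=per_tissue,
        per_staining=per_staining,
        n_with_segmentation=n_seg,
        unreadable=unreadable,
    )
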