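"""Top-level orchestration: canned experiments, deposit statistics and the CLI.

``run_experiment`` wires the whole pipeline together: dataset (on-disk or a
synthetic preset) -> stratified folds -> per-fold training of the chosen
model family -> prediction on the held-out fold -> metrics, with every
score passed through the identity cross-score conversion for the
off-diagonal report columns.  All stage seeds derive from one base seed by
stable hashing, and every experiment directory records config and seeds so
its report can be regenerated byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import dataset_io, evaluation, regression_model, segmentation_model
from . import synthetic_histology as synth
from .data_pipeline import downsample
from .scores import ScorePair, UndefinedScoreError, cross_score, s_area_from_mask

DEFAULT_SEED = 42


def derive_seed(base: int, *parts) -> int:
    """Stable stage seed from (base, experiment, stage, fold, repeat...)."""
    h = hashlib.sha256(("/".join(str(p) for p in parts) + f"#{base}").encode())
    return int.from_bytes(h.digest()[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    dataset: str = "synthetic:smoke"
    task: str = "segmentation"  # regression | masked_regression | segmentation
    k_folds: int = 3
    repeats: int = 1
    seed: int = DEFAULT_SEED
    output_dir: str = "experiment"
    base_width: int = 16
    epochs: int = 5
    steps_per_epoch: int = 20
    batch_size: int = 8
    learning_rate: float = 0.01
    width_scale: float = 0.25

    def __post_init__(self):
        if self.task not in ("regression", "masked_regression", "segmentation"):
            raise ValueError(f"unknown task {self.task!r}")


#: synthetic presets: generation size and image geometry
SYNTHETIC_PRESETS = {
    "smoke": {"n": 12, "height_px": 64, "width_px": 64, "seg_share": 1.0},
    "desk": {"n": 80, "height_px": 256, "width_px": 256, "seg_share": 1.0},
}


def _materialize_dataset(config: ExperimentConfig, out_dir: Path):
    if config.dataset.startswith("synthetic:"):
        preset = config.dataset.split(":", 1)[1]
        if preset not in SYNTHETIC_PRESETS:
            raise ValueError(f"unknown synthetic preset {preset!r}")
        p = SYNTHETIC_PRESETS[preset]
        strata = dict(synth.DEFAULT_STRATA)
        strata["segmentation_share"] = p["seg_share"]
        template = synth.GeneratorConfig(height_px=p["height_px"], width_px=p["width_px"])
        data_dir = out_dir / "data"
        manifest = synth.generate_dataset(
            p["n"], data_dir, strata=strata, config_template=template,
            seed=derive_seed(config.seed, config.dataset, "generate"))
        return manifest
    return dataset_io.load_manifest(Path(config.dataset))


def _eval_segmentation(manifest, train_ids, test_ids, fold, rep, config):
    seed = derive_seed(config.seed, "seg", fold, rep)
    ucfg = segmentation_model.UNetConfig(
        base_width=config.base_width, epochs=config.epochs,
        steps_per_epoch=config.steps_per_epoch, batch_size=config.batch_size,
        learning_rate=config.learning_rate, seed=seed,
        allow_any_width=True)
    train_masked = [s for s in train_ids if manifest.by_id(s).has_segmentation]
    models, _ = segmentation_model.train_segmenter(manifest, train_masked, ucfg, repeats=1)
    model = models[0]
    ious, accs, pred_area, true_area, true_nuc = [], [], [], [], []
    for sid in test_ids:
        rec = manifest.by_id(sid)
        if not rec.has_segmentation:
            continue
        image, mask = dataset_io.load_sample(rec, manifest.palette)
        labels, _ = segmentation_model.predict_mask(model, image, ucfg)
        ious.append(evaluation.macro_iou(labels, mask))
        accs.append(evaluation.pixel_accuracy(labels, mask))
        try:
            pair, _ = s_area_from_mask(labels)
            pred_area.append(pair.s_area)
        except UndefinedScoreError:
            pred_area.append(0.0)  # flagged failure, scored against truth anyway
        true_area.append(rec.s_area)
        true_nuc.append(rec.s_nuclei)
    mae_area, _ = evaluation.mae_stats(pred_area, true_area)
    cross = [cross_score(ScorePair(s_area=p), "nuclei") for p in pred_area]
    mae_nuc, _ = evaluation.mae_stats(cross, true_nuc)
    return {"iou": float(np.mean(ious)), "acc": float(np.mean(accs)),
            "mae_s_area": mae_area, "mae_s_nuclei": mae_nuc}


def _eval_regression(manifest, train_ids, test_ids, fold, rep, config, masked: bool):
    seed = derive_seed(config.seed, "reg", fold, rep)
    rcfg = regression_model.RegressorConfig(
        width_scale=config.width_scale, epochs=config.epochs,
        steps_per_epoch=config.steps_per_epoch, batch_size=config.batch_size,
        learning_rate=config.learning_rate, seed=seed)
    masker = None
    mcfg = None
    if masked:
        mcfg = regression_model.MaskerConfig(
            encoder_widths=(8, 16, 32), epochs=config.epochs,
            batches_per_epoch=config.steps_per_epoch,
            batch_size=config.batch_size, learning_rate=config.learning_rate,
            seed=derive_seed(config.seed, "masker", fold, rep))
        train_masked = [s for s in train_ids if manifest.by_id(s).has_segmentation]
        masker, _ = regression_model.build_and_train_masker(manifest, train_masked, mcfg)
    model, _ = regression_model.train_regressor(
        manifest, train_ids, "s_nuclei", rcfg, masker=masker, masker_config=mcfg)
    preds, truth_nuc, pred_m, truth_area = [], [], [], []
    for sid in test_ids:
        rec = manifest.by_id(sid)
        image, _ = dataset_io.load_sample(rec, manifest.palette)
        p = regression_model.predict_score(model, image, rcfg, masker=masker,
                                           masker_config=mcfg)
        preds.append(p)
        truth_nuc.append(rec.s_nuclei)
        if rec.s_area is not None:
            pred_m.append(cross_score(ScorePair(s_nuclei=p), "area"))
            truth_area.append(rec.s_area)
    mae_nuc, _ = evaluation.mae_stats(preds, truth_nuc)
    out = {"mae_s_nuclei": mae_nuc}
    if truth_area:
        mae_area, _ = evaluation.mae_stats(pred_m, truth_area)
        out["mae_s_area"] = mae_area
    return out


def run_experiment(config: ExperimentConfig) -> Path:
    """Run one canned experiment end to end; returns the output directory."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _materialize_dataset(config, out_dir)
    if config.task == "segmentation":
        if not any(r.has_segmentation for r in manifest.records):
            raise ValueError("segmentation task needs a manifest with masks")
    folds = evaluation.stratified_folds(
        manifest, k=config.k_folds, seed=derive_seed(config.seed, "folds"))

    def evaluate_fold(train_ids, test_ids, fold, rep):
        if config.task == "segmentation":
            return _eval_segmentation(manifest, train_ids, test_ids, fold, rep, config)
        return _eval_regression(manifest, train_ids, test_ids, fold, rep, config,
                                masked=config.task == "masked_regression")

    report = evaluation.cross_validate_report(config.task, manifest, folds,
                                              evaluate_fold, repeats=config.repeats)
    report.to_frame().to_csv(out_dir / "report.csv")
    payload = {
        "config": asdict(config),
        "seeds": {"base": config.seed,
                  "folds": derive_seed(config.seed, "folds"),
                  "per_fold": {str(f): derive_seed(config.seed,
                                                   "seg" if config.task == "segmentation" else "reg",
                                                   f, 0)
                               for f in range(config.k_folds)}},
        "aggregate": {k: [float(v["mean"]), float(v["sd"])]
                      for k, v in report.aggregate().to_dict("index").items()},
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return out_dir


# ---------------------------------------------------------------------------
# deposit statistics (no training involved)
# ---------------------------------------------------------------------------


def deposit_statistics(deposit_dir: str | Path) -> dict:
    """Annotation statistics of a dataset in the standard layout.

    Computes per-stratum counts, S_area recomputed from every mask, its
    MAE/sd against the annotated S_nuclei over all masked samples and over
    the critical subset 0.1 <= S_nuclei <= 0.9, and — when a second
    annotator column ``s_nuclei_2`` is present — the annotator-pair MAE.
    """
    deposit_dir = Path(deposit_dir)
    manifest_path = deposit_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"unrecognized deposit layout under {deposit_dir}: expected "
            "manifest.csv (+ optional dataset.yaml) with images/ and masks/")
    manifest = dataset_io.load_manifest(manifest_path)
    report = dataset_io.validate_dataset(manifest)
    s_area_vals, s_nuclei_vals = [], []
    for rec in manifest.records:
        if not rec.has_segmentation:
            continue
        _, mask = dataset_io.load_sample(rec, manifest.palette)
        pair, _ = s_area_from_mask(mask)
        s_area_vals.append(pair.s_area)
        s_nuclei_vals.append(rec.s_nuclei)
    out = {
        "n": report.n,
        "per_tissue": report.per_tissue,
        "per_staining": report.per_staining,
        "n_with_segmentation": report.n_with_segmentation,
        "unreadable": report.unreadable,
    }
    if s_area_vals:
        mae, sd = evaluation.mae_stats(s_area_vals, s_nuclei_vals)
        out["s_area_vs_s_nuclei"] = {"mae": mae, "sd": sd, "n": len(s_area_vals)}
        a = np.asarray(s_area_vals)
        t = np.asarray(s_nuclei_vals)
        crit = (t >= 0.1) & (t <= 0.9)
        if crit.any():
            mae_c, sd_c = evaluation.mae_stats(a[crit], t[crit])
            out["s_area_vs_s_nuclei_critical"] = {
                "mae": mae_c, "sd": sd_c, "n": int(crit.sum())}
    df = pd.read_csv(manifest_path)
    if "s_nuclei_2" in df.columns:
        dual = df.dropna(subset=["s_nuclei_2"])
        if len(dual) >= 2:
            mae, sd = evaluation.mae_stats(dual["s_nuclei"], dual["s_nuclei_2"])
            out["pathologist_pair"] = {"mae": mae, "sd": sd, "n": int(len(dual))}
    return out


def critical_subset(scores, lo: float = 0.1, hi: float = 0.9) -> np.ndarray:
    """Boolean mask of the heterogeneity-critical score range [lo, hi]."""
    s = np.asarray(scores, dtype=float)
    return (s >= lo) & (s <= hi)


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------


@click.group()
def cli():
    """Damage quantification in stained epidermis histology."""


@cli.command()
@click.option("--n", type=int, default=80)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--seed", type=int, default=DEFAULT_SEED)
@click.option("--size", type=int, default=256, help="image side in pixels")
@click.option("--low-contrast", is_flag=True)
def synth_cmd(n, out_dir, seed, size, low_contrast):
    """Generate a synthetic stained-epidermis dataset."""
    template = synth.GeneratorConfig(height_px=size, width_px=size,
                                     contrast=0.35 if low_contrast else 1.0)
    manifest = synth.generate_dataset(n, out_dir, config_template=template, seed=seed)
    click.echo(f"wrote {len(manifest)} samples to {out_dir}")


cli.add_command(synth_cmd, name="synth")


@cli.command()
@click.option("--manifest", "manifest_path", type=click.Path(exists=True), required=True)
def validate(manifest_path):
    """Validate a dataset manifest and print stratum counts."""
    manifest = dataset_io.load_manifest(manifest_path)
    report = dataset_io.validate_dataset(manifest)
    click.echo(json.dumps({
        "n": report.n, "per_tissue": report.per_tissue,
        "per_staining": report.per_staining,
        "n_with_segmentation": report.n_with_segmentation,
        "unreadable": report.unreadable}, indent=2))


@cli.command("train-seg")
@click.option("--manifest", "manifest_path", type=click.Path(exists=True), required=True)
@click.option("--width", type=int, default=64)
@click.option("--epochs", type=int, default=50)
@click.option("--steps", type=int, default=100)
@click.option("--batch", type=int, default=32)
@click.option("--repeats", type=int, default=5)
@click.option("--seed", type=int, default=DEFAULT_SEED)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def train_seg(manifest_path, width, epochs, steps, batch, repeats, seed, out_dir):
    """Train 3-class damage U-Net(s) on all masked samples."""
    manifest = dataset_io.load_manifest(manifest_path)
    cfg = segmentation_model.UNetConfig(base_width=width, epochs=epochs,
                                        steps_per_epoch=steps, batch_size=batch,
                                        seed=seed, allow_any_width=True)
    models, histories = segmentation_model.train_segmenter(manifest, None, cfg,
                                                           repeats=repeats)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for r, (model, hist) in enumerate(zip(models, histories)):
        np.savez(out / f"unet{width}_rep{r}.npz",
                 **{f"p{i}": p.w for i, p in enumerate(model.parameters())})
        pd.DataFrame({"epoch": range(1, len(hist) + 1), "loss": hist}).to_csv(
            out / f"history_rep{r}.csv", index=False)
    click.echo(f"trained {repeats} model(s) -> {out_dir}")


@cli.command("train-reg")
@click.option("--manifest", "manifest_path", type=click.Path(exists=True), required=True)
@click.option("--target", type=click.Choice(["s_nuclei", "s_area"]), default="s_nuclei")
@click.option("--masked", is_flag=True)
@click.option("--epochs", type=int, default=50)
@click.option("--steps", type=int, default=100)
@click.option("--batch", type=int, default=32)
@click.option("--seed", type=int, default=DEFAULT_SEED)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def train_reg(manifest_path, target, masked, epochs, steps, batch, seed, out_dir):
    """Train the score regressor (optionally epidermis-masked)."""
    manifest = dataset_io.load_manifest(manifest_path)
    rcfg = regression_model.RegressorConfig(epochs=epochs, steps_per_epoch=steps,
                                            batch_size=batch, seed=seed)
    masker = None
    mcfg = None
    if masked:
        mcfg = regression_model.MaskerConfig(seed=seed + 1)
        masker, _ = regression_model.build_and_train_masker(manifest, None, mcfg)
    model, hist = regression_model.train_regressor(manifest, None, target, rcfg,
                                                   masker=masker, masker_config=mcfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "regressor.npz",
             **{f"p{i}": p.w for i, p in enumerate(model.parameters())})
    pd.DataFrame({"epoch": range(1, len(hist) + 1), "loss": hist}).to_csv(
        out / "history.csv", index=False)
    click.echo(f"trained regressor -> {out_dir}")


@cli.command()
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--image", "image_path", type=click.Path(exists=True), required=True)
@click.option("--width", type=int, default=64)
@click.option("--out", "out_path", type=click.Path(), required=True)
def predict(model_path, image_path, width, out_path):
    """Predict a damage mask (paletted PNG) + JSON with S_area and areas."""
    from PIL import Image
    cfg = segmentation_model.UNetConfig(base_width=width, allow_any_width=True)
    model = segmentation_model.build_unet(cfg)
    data = np.load(model_path)
    for i, p in enumerate(model.parameters()):
        p.w[...] = data[f"p{i}"]
    image = np.asarray(Image.open(image_path).convert("RGB"), dtype=np.uint8)
    labels, _ = segmentation_model.predict_mask(model, image, cfg)
    dataset_io.write_mask_png(labels, out_path)
    try:
        pair, areas = s_area_from_mask(labels)
        info = {"s_area": pair.s_area, "a_dmg": areas.a_dmg, "a_epi": areas.a_epi}
    except UndefinedScoreError:
        info = {"s_area": None, "flag": "no epidermis predicted"}
    with open(Path(out_path).with_suffix(".json"), "w") as fh:
        json.dump(info, fh, indent=2)
    click.echo(json.dumps(info))


@cli.command("eval")
@click.option("--pred", "pred_csv", type=click.Path(exists=True), required=True)
@click.option("--truth", "truth_csv", type=click.Path(exists=True), required=True)
@click.option("--column", default="score")
def eval_cmd(pred_csv, truth_csv, column):
    """MAE statistics between two per-sample score tables."""
    p = pd.read_csv(pred_csv)[column]
    t = pd.read_csv(truth_csv)[column]
    mae, sd = evaluation.mae_stats(p, t)
    click.echo(json.dumps({"mae": mae, "sd": sd, "n": int(len(p))}))


@cli.command()
@click.option("--a", "a_csv", type=click.Path(exists=True), required=True)
@click.option("--b", "b_csv", type=click.Path(exists=True), required=True)
@click.option("--n", "n_boot", type=int, default=1000)
@click.option("--seed", type=int, default=DEFAULT_SEED)
@click.option("--column", default="score")
@click.option("--out", "out_path", type=click.Path(), required=True)
def bootstrap(a_csv, b_csv, n_boot, seed, column, out_path):
    """Paired bootstrap of the agreement between two raters."""
    a = pd.read_csv(a_csv)[column]
    b = pd.read_csv(b_csv)[column]
    dist = evaluation.bootstrap_agreement(a, b, n_boot=n_boot, seed=seed)
    with open(out_path, "w") as fh:
        json.dump({"scenario": dist.scenario, "n_boot": dist.n_boot,
                   "seed": dist.seed,
                   "mae_samples": dist.mae_samples.tolist(),
                   "sd_samples": dist.sd_samples.tolist()}, fh)
    click.echo(f"MAE {dist.mae_samples.mean():.4f} "
               f"[{np.quantile(dist.mae_samples, 0.025):.4f}, "
               f"{np.quantile(dist.mae_samples, 0.975):.4f}]")


@cli.command()
@click.option("--manifest", "manifest_path", type=click.Path(exists=True), required=True)
@click.option("--k", type=int, default=10)
@click.option("--seed", type=int, default=DEFAULT_SEED)
def cv(manifest_path, k, seed):
    """Print the stratified fold assignment."""
    manifest = dataset_io.load_manifest(manifest_path)
    folds = evaluation.stratified_folds(manifest, k=k, seed=seed)
    click.echo(json.dumps(folds.fold_of, indent=2, sort_keys=True))


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--dataset", default=None)
@click.option("--task", default=None)
@click.option("--out", "out_dir", default=None)
@click.option("--seed", type=int, default=None)
def run(config_path, dataset, task, out_dir, seed):
    """Run a canned end-to-end experiment (YAML config and/or overrides)."""
    kwargs = {}
    if config_path:
        with open(config_path) as fh:
            kwargs.update(yaml.safe_load(fh) or {})
    for key, val in (("dataset", dataset), ("task", task),
                     ("output_dir", out_dir), ("seed", seed)):
        if val is not None:
            kwargs[key] = val
    out = run_experiment(ExperimentConfig(**kwargs))
    click.echo(f"experiment written to {out}")


@cli.command("deposit-stats")
@click.option("--deposit", "deposit_dir", type=click.Path(exists=True), required=True)
def deposit_stats(deposit_dir):
    """Annotation statistics of a deposited dataset (no training)."""
    click.echo(json.dumps(deposit_statistics(deposit_dir), indent=2, sort_keys=True))
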