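"""Metrics and statistical procedures for the damage-scoring study.

Covers the error statistics on scalar scores (mean and population standard
deviation of absolute errors), the 3-class segmentation metrics
(macro-averaged Jaccard index and pixel accuracy), stratified k-fold
construction emphasizing staining, tissue and mask availability, and the
paired bootstrap used to compare model-vs-annotator against
annotator-vs-annotator agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scores import MASK_CLASSES

# ---------------------------------------------------------------------------
# scalar-score error statistics
# ---------------------------------------------------------------------------


def mae_stats(pred, truth) -> tuple[float, float]:
    """Mean and population standard deviation of absolute errors |pred - truth|."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("need at least one pair")
    err = np.abs(pred - truth)
    return float(err.mean()), float(err.std())


# ---------------------------------------------------------------------------
# segmentation metrics
# ---------------------------------------------------------------------------


def macro_iou(pred: np.ndarray, truth: np.ndarray, classes=MASK_CLASSES) -> float:
    """Unweighted mean of per-class Jaccard indices over all three classes.

    A class absent from both masks contributes 1.0, so the macro average is
    always over exactly ``len(classes)`` terms.  Predicting even a few
    pixels of a class that the ground truth does not contain therefore
    drags the macro average down — the behaviour seen on nearly-perfect
    predictions of fully damaged samples.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    vals = []
    for c in classes:
        p = pred == c
        t = truth == c
        union = int(np.logical_or(p, t).sum())
        if union == 0:
            vals.append(1.0)
        else:
            vals.append(int(np.logical_and(p, t).sum()) / union)
    return float(np.mean(vals))


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return float((pred == truth).mean())


# ---------------------------------------------------------------------------
# stratified k-fold construction
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    k: int
    fold_of: dict[str, int]
    strata_key: tuple[str, ...] = ("staining", "tissue", "has_segmentation")

    def fold_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.fold_of.items() if f == fold]


def stratified_folds(manifest, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Deal samples to ``k`` folds, stratified by (staining, tissue, has-mask).

    Within each stratum the samples are shuffled and dealt round-robin; the
    dealing position carries over between strata so per-stratum fold counts
    and total fold sizes both differ by at most one.
    """
    records = getattr(manifest, "records", manifest)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(records):
        raise ValueError(f"k={k} exceeds number of samples {len(records)}")
    rng = np.random.default_rng(seed)
    strata: dict[tuple, list[str]] = {}
    for rec in records:
        key = (rec.staining, rec.tissue, rec.has_segmentation)
        strata.setdefault(key, []).append(rec.sample_id)
    fold_of: dict[str, int] = {}
    pos = 0
    for key in sorted(strata, key=repr):
        ids = strata[key]
        order = rng.permutation(len(ids))
        for j in order:
            fold_of[ids[j]] = pos % k
            pos += 1
    return FoldAssignment(k=k, fold_of=fold_of)


# ---------------------------------------------------------------------------
# bootstrap agreement analysis
# ---------------------------------------------------------------------------


@dataclass
class AgreementDistribution:
    """Bootstrap distribution of (MAE, sd of |errors|) for one scoring pair."""

    scenario: str
    n_boot: int
    mae_samples: np.ndarray
    sd_samples: np.ndarray
    seed: int


def bootstrap_agreement(scores_a, scores_b, n_boot: int = 1000, seed: int = 0,
                        scenario: str = "pair") -> AgreementDistribution:
    """Nonparametric paired bootstrap of the agreement between two raters.

    Each replicate resamples the n score pairs with replacement and
    recomputes :func:`mae_stats`.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired scores")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    err = np.abs(a[idx] - b[idx])
    return AgreementDistribution(
        scenario=scenario,
        n_boot=n_boot,
        mae_samples=err.mean(axis=1),
        sd_samples=err.std(axis=1),
        seed=seed,
    )


def dominance_fraction(lower: AgreementDistribution, upper: AgreementDistribution) -> float:
    """Fraction of paired bootstrap draws where ``lower``'s MAE < ``upper``'s."""
    return float(np.mean(lower.mae_samples < upper.mae_samples))


# ---------------------------------------------------------------------------
# cross-validated reporting
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    """Per-fold metrics plus their mean +/- sd aggregate, one model."""

    model: str
    per_fold: pd.DataFrame = field(repr=False)

    def aggregate(self) -> pd.DataFrame:
        num = self.per_fold.select_dtypes("number")
        out = pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=0)})
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = self.per_fold.copy()
        agg = {c: f"{m:.3f} ± {s:.3f}" for c, (m, s) in self.aggregate().iterrows()}
        rows.loc["all"] = agg
        rows.insert(0, "model", self.model)
        return rows


def cross_validate_report(model_name: str, manifest, folds: FoldAssignment,
                          evaluate_fold, repeats: int = 1) -> MetricReport:
    """Run ``evaluate_fold(train_ids, test_ids, fold, repeat) -> dict`` over all folds.

    ``evaluate_fold`` trains (or loads) a model on the training ids and
    returns a metric dict; segmentation protocols pass ``repeats`` > 1 and
    are called once per (fold, repeat).  Metrics are aggregated as mean and
    population sd across all calls.
    """
    rows = []
    for fold in range(folds.k):
        test_ids = folds.fold_ids(fold)
        train_ids = [sid for sid, f in folds.fold_of.items() if f != fold]
        if not test_ids:
            raise ValueError(f"fold {fold} is empty")
        for rep in range(repeats):
            metrics = evaluate_fold(train_ids, test_ids, fold, rep)
            rows.append({"fold": fold, "repeat": rep, **metrics})
    df = pd.DataFrame(rows).set_index(["fold", "repeat"])
    return MetricReport(model=model_name, per_fold=df)
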