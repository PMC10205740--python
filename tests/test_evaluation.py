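from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiderm import evaluation as ev
from epiderm.dataset_io import SampleRecord
from epiderm.synthetic_histology import DEFAULT_STRATA, draw_strata


def brute_force_iou(pred, truth):
    vals = []
    for c in (0, 1, 2):
        p = {tuple(ix) for ix in np.argwhere(pred == c)}
        t = {tuple(ix) for ix in np.argwhere(truth == c)}
        u = p | t
        vals.append(1.0 if not u else len(p & t) / len(u))
    return sum(vals) / 3


def make_records(n, seed=3):
    return [
        SampleRecord(f"s{i:04d}", Path("img.png"), tissue, staining, 0.5,
                     Path("m.png") if seg else None)
        for i, (tissue, staining, seg) in enumerate(draw_strata(n, DEFAULT_STRATA, seed))
    ]


class TestMaeStats:
    def test_identical_vectors(self):
        assert ev.mae_stats([0.1, 0.4], [0.1, 0.4]) == (0.0, 0.0)

    def test_constant_offset(self):
        mean, sd = ev.mae_stats([0.2, 0.5, 0.8], [0.1, 0.4, 0.7])
        assert mean == pytest.approx(0.1)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        mean, sd = ev.mae_stats([0.1, 0.5, 0.9], [0.2, 0.4, 0.6])
        assert mean == pytest.approx(0.16667, abs=1e-4)
        assert sd == pytest.approx(0.09428, abs=1e-4)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ev.mae_stats([0.1], [0.1, 0.2])


class TestSegmentationMetrics:
    def test_identical_masks(self, rng):
        m = rng.integers(0, 3, (8, 8))
        assert ev.macro_iou(m, m) == 1.0
        assert ev.pixel_accuracy(m, m) == 1.0

    def test_worked_example(self):
        truth = np.array([[0, 1, 1, 2]])
        pred = np.array([[0, 1, 2, 2]])
        assert ev.macro_iou(pred, truth) == pytest.approx(2 / 3, abs=1e-5)
        assert ev.pixel_accuracy(pred, truth) == 0.75

    def test_absent_in_both_class_scores_one(self):
        truth = np.ones((2, 2), np.uint8)
        assert ev.macro_iou(truth, truth) == 1.0

    def test_spurious_absent_class_penalized(self):
        truth = np.full((10, 10), 2, np.uint8)
        pred = truth.copy()
        pred[0, :3] = 1  # small spurious healthy prediction
        assert ev.macro_iou(pred, truth) < 0.8

    def test_all_labels_differ(self):
        assert ev.pixel_accuracy(np.zeros((3, 3)), np.ones((3, 3))) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ev.macro_iou(np.zeros((2, 2)), np.zeros((3, 3)))

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_against_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        pred = r.integers(0, 3, (16, 16))
        truth = r.integers(0, 3, (16, 16))
        assert ev.macro_iou(pred, truth) == pytest.approx(brute_force_iou(pred, truth))
        assert ev.pixel_accuracy(pred, truth) == pytest.approx(
            np.mean([p == t for p, t in zip(pred.ravel(), truth.ravel())]))


class TestStratifiedFolds:
    def test_two_balanced_strata(self):
        recs = []
        for i in range(10):
            recs.append(SampleRecord(f"a{i}", Path("x"), "human_skin", "CPD", 0.5))
        for i in range(10):
            recs.append(SampleRecord(f"b{i}", Path("x"), "porcine_skin", "64PP", 0.5))
        folds = ev.stratified_folds(recs, k=10, seed=1)
        for f in range(10):
            ids = folds.fold_ids(f)
            assert len(ids) == 2
            assert len({i[0] for i in ids}) == 2  # one from each stratum

    def test_partition(self):
        recs = make_records(57)
        folds = ev.stratified_folds(recs, k=5, seed=2)
        assert sorted(folds.fold_of) == sorted(r.sample_id for r in recs)

    def test_tiny_stratum_spread(self):
        recs = [SampleRecord(f"c{i}", Path("x"), "human_skin", "CPD", 0.5)
                for i in range(17)]
        recs += [SampleRecord(f"r{i}", Path("x"), "porcine_skin", "MAA", 0.5)
                 for i in range(3)]
        folds = ev.stratified_folds(recs, k=10, seed=0)
        rare = [folds.fold_of[f"r{i}"] for i in range(3)]
        assert len(set(rare)) == 3  # three folds get one member each

    def test_k_validation(self):
        recs = make_records(10)
        with pytest.raises(ValueError):
            ev.stratified_folds(recs, k=1)
        with pytest.raises(ValueError):
            ev.stratified_folds(recs, k=11)


class TestBootstrap:
    def test_identical_scores(self):
        d = ev.bootstrap_agreement([0.1] * 5, [0.1] * 5, n_boot=50, seed=0)
        assert np.all(d.mae_samples == 0)

    def test_constant_offset(self):
        a = np.linspace(0, 0.5, 8)
        d = ev.bootstrap_agreement(a + 0.1, a, n_boot=100, seed=0)
        assert np.allclose(d.mae_samples, 0.1)
        assert np.allclose(d.sd_samples, 0.0)

    def test_deterministic(self):
        a = np.linspace(0, 1, 10)
        b = a[::-1]
        d1 = ev.bootstrap_agreement(a, b, n_boot=200, seed=7)
        d2 = ev.bootstrap_agreement(a, b, n_boot=200, seed=7)
        assert np.array_equal(d1.mae_samples, d2.mae_samples)

    def test_mean_converges_to_mae(self, rng):
        a = rng.uniform(0, 1, 60)
        b = rng.uniform(0, 1, 60)
        mae, sd = ev.mae_stats(a, b)
        d = ev.bootstrap_agreement(a, b, n_boot=2000, seed=3)
        se = d.mae_samples.std() / np.sqrt(2000) + sd / np.sqrt(60)
        assert abs(d.mae_samples.mean() - mae) < 3 * se

    def test_too_short(self):
        with pytest.raises(ValueError):
            ev.bootstrap_agreement([0.1], [0.2])


class TestCrossValidateReport:
    def test_shapes_and_aggregate(self):
        recs = make_records(20)
        folds = ev.stratified_folds(recs, k=4, seed=0)

        def fake_eval(train_ids, test_ids, fold, rep):
            assert set(train_ids).isdisjoint(test_ids)
            return {"mae": 0.1, "iou": 0.8}

        report = ev.cross_validate_report("stub", recs, folds, fake_eval, repeats=2)
        assert len(report.per_fold) == 8  # 4 folds x 2 repeats
        agg = report.aggregate()
        assert agg.loc["mae", "mean"] == pytest.approx(0.1)
        assert agg.loc["mae", "sd"] == pytest.approx(0.0)
        frame = report.to_frame()
        assert "all" in frame.index
        assert (frame["model"] == "stub").all()
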