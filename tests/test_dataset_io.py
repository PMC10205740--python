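import numpy as np
import pandas as pd
import pytest
from PIL import Image

from epiderm import dataset_io as dio
from epiderm.synthetic_histology import DEFAULT_STRATA, draw_strata


class TestManifestRoundTrip:
    def test_round_trip_identity(self, ds_small, tmp_path):
        loaded = dio.load_manifest(ds_small.records[0].image_path.parent.parent
                                   / "manifest.csv")
        assert len(loaded) == len(ds_small)
        for a, b in zip(loaded.records, ds_small.records):
            assert a.sample_id == b.sample_id
            assert a.tissue == b.tissue and a.staining == b.staining
            assert a.s_nuclei == pytest.approx(b.s_nuclei)
            assert a.has_segmentation == b.has_segmentation
            assert (a.s_area is None) == (b.s_area is None)
            if a.s_area is not None:
                assert a.s_area == pytest.approx(b.s_area)
        assert loaded.resolution_um_per_px == ds_small.resolution_um_per_px

    def test_missing_column_is_schema_error(self, tmp_path):
        pd.DataFrame({"sample_id": ["a"], "image": ["x.png"]}).to_csv(
            tmp_path / "manifest.csv", index=False)
        with pytest.raises(dio.ManifestSchemaError, match="tissue"):
            dio.load_manifest(tmp_path / "manifest.csv")

    def test_score_out_of_range_rejected(self, tmp_path):
        pd.DataFrame({
            "sample_id": ["a"], "image": ["x.png"], "tissue": ["human_skin"],
            "staining": ["CPD"], "s_nuclei": [1.3],
        }).to_csv(tmp_path / "manifest.csv", index=False)
        with pytest.raises(dio.ManifestValidationError, match="1.3"):
            dio.load_manifest(tmp_path / "manifest.csv")

    def test_duplicate_id_rejected(self, tmp_path):
        pd.DataFrame({
            "sample_id": ["a", "a"], "image": ["x.png", "y.png"],
            "tissue": ["human_skin"] * 2, "staining": ["CPD"] * 2,
            "s_nuclei": [0.1, 0.2],
        }).to_csv(tmp_path / "manifest.csv", index=False)
        with pytest.raises(dio.ManifestValidationError, match="duplicate"):
            dio.load_manifest(tmp_path / "manifest.csv")

    def test_deposit_scale_mask_availability(self, tmp_path):
        # manifest emulating the full deposit: 804 rows, 202 with masks
        rows = []
        for i, (tissue, staining, seg) in enumerate(
                draw_strata(804, DEFAULT_STRATA, seed=4)):
            rows.append({"sample_id": f"s{i:04d}", "image": f"images/s{i:04d}.png",
                         "tissue": tissue, "staining": staining, "s_nuclei": 0.5,
                         "mask": f"masks/s{i:04d}.png" if seg else ""})
        pd.DataFrame(rows).to_csv(tmp_path / "manifest.csv", index=False)
        manifest = dio.load_manifest(tmp_path / "manifest.csv")
        assert len(manifest) == 804
        assert sum(r.has_segmentation for r in manifest.records) == 202

    def test_exclusion_list_applies(self, ds_small, tmp_path):
        import yaml
        src = ds_small.records[0].image_path.parent.parent
        man = dio.load_manifest(src / "manifest.csv")
        out = tmp_path / "manifest.csv"
        dio.write_manifest(man, out)
        with open(tmp_path / "dataset.yaml") as fh:
            meta = yaml.safe_load(fh)
        meta["exclude_ids"] = [man.records[0].sample_id, man.records[1].sample_id]
        with open(tmp_path / "dataset.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)
        reloaded = dio.load_manifest(out)
        assert len(reloaded) == len(man) - 2


class TestLoadSample:
    def test_paletted_mask_decodes_to_classes(self, ds_small):
        rec = next(r for r in ds_small.records if r.has_segmentation)
        image, mask = dio.load_sample(rec)
        assert image.dtype == np.uint8 and image.shape[2] == 3
        assert set(np.unique(mask)) <= {0, 1, 2}

    def test_rgb_mask_decoded_via_palette(self, tmp_path):
        rgb = np.zeros((4, 4, 3), np.uint8)
        rgb[0] = dio.MASK_PALETTE[1]
        rgb[1] = dio.MASK_PALETTE[2]
        Image.fromarray(rgb).save(tmp_path / "m.png")
        Image.fromarray(np.zeros((4, 4, 3), np.uint8)).save(tmp_path / "i.png")
        rec = dio.SampleRecord("x", tmp_path / "i.png", "human_skin", "CPD", 0.5,
                               mask_path=tmp_path / "m.png")
        _, mask = dio.load_sample(rec)
        assert list(np.unique(mask)) == [0, 1, 2]
        assert (mask[0] == 1).all() and (mask[1] == 2).all()

    def test_shape_mismatch_raises(self, tmp_path):
        Image.fromarray(np.zeros((8, 8, 3), np.uint8)).save(tmp_path / "i.png")
        dio.write_mask_png(np.zeros((4, 4), np.uint8), tmp_path / "m.png")
        rec = dio.SampleRecord("x", tmp_path / "i.png", "human_skin", "CPD", 0.5,
                               mask_path=tmp_path / "m.png")
        with pytest.raises(ValueError, match="shape"):
            dio.load_sample(rec)

    def test_unknown_mask_value_named(self, tmp_path):
        Image.fromarray(np.zeros((4, 4, 3), np.uint8)).save(tmp_path / "i.png")
        bad = np.full((4, 4), 7, np.uint8)
        Image.fromarray(bad, mode="L").save(tmp_path / "m.png")
        rec = dio.SampleRecord("x", tmp_path / "i.png", "human_skin", "CPD", 0.5,
                               mask_path=tmp_path / "m.png")
        with pytest.raises(ValueError, match="unknown mask value 7"):
            dio.load_sample(rec)


class TestValidateDataset:
    def test_counts_match_generation(self, ds_small):
        report = dio.validate_dataset(ds_small)
        assert report.n == 12
        assert sum(report.per_tissue.values()) == 12
        assert report.n_with_segmentation == 12
        assert report.unreadable == []

    def test_empty_manifest(self):
        report = dio.validate_dataset(dio.DatasetManifest(records=[]))
        assert report.n == 0
        assert all(v == 0 for v in report.per_tissue.values())

    def test_missing_file_reported_not_raised(self, ds_small, tmp_path):
        broken = dio.DatasetManifest(records=[
            dio.SampleRecord("gone", tmp_path / "nope.png", "human_skin", "CPD", 0.5)
        ] + list(ds_small.records[:3]))
        report = dio.validate_dataset(broken)
        assert any("nope.png" in u for u in report.unreadable)
        assert report.n == 4
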