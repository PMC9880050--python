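"""Image/mask loading, flip + translate augmentation counts, split
protocols, and leakage freedom."""

import numpy as np
import pytest

from fpmnet.config import ConfigurationError
from fpmnet.data import (DATASET_PROFILES, SplitProtocol, ValidationError,
                         flip_augment, load_manifest, load_pair, make_splits,
                         save_manifest, translate_augment, write_pair,
                         _translate)
from fpmnet import SampleRecord

import imageio.v3 as iio


@pytest.fixture
def png_pair(tmp_path):
    rng = np.random.default_rng(0)
    img = (rng.random((40, 30, 3)) * 255).astype(np.uint8)
    raw_mask = np.where(rng.random((40, 30)) > 0.8, 255, 0).astype(np.uint8)
    ip, mp = tmp_path / "img.png", tmp_path / "mask.png"
    iio.imwrite(ip, img)
    iio.imwrite(mp, raw_mask)
    return ip, mp, img, raw_mask


class TestLoadPair:
    def test_scaling_and_binarization(self, png_pair):
        ip, mp, img, raw = png_pair
        rec = load_pair(ip, mp)
        assert rec.image.dtype == np.float32
        assert rec.image.max() <= 1.0 and rec.image.min() >= 0.0
        assert set(np.unique(rec.mask)) <= {0, 1}
        assert np.array_equal(rec.mask, (raw > 0).astype(np.uint8))

    def test_size_mismatch_rejected(self, png_pair, tmp_path):
        ip, mp, *_ = png_pair
        bad = tmp_path / "bad_mask.png"
        iio.imwrite(bad, np.zeros((40, 28), dtype=np.uint8))
        with pytest.raises(ValidationError, match="sizes differ"):
            load_pair(ip, bad)

    def test_unreadable_file_reports_path(self, tmp_path):
        with pytest.raises(IOError, match="missing.png"):
            load_pair(tmp_path / "missing.png", tmp_path / "missing.png")


class TestFlipAugment:
    def test_counts(self, tiny_records):
        assert len(flip_augment(tiny_records)) == 60
        assert len(flip_augment(tiny_records[:1])) == 3

    def test_flip_applied_identically_and_involutive(self, tiny_records):
        out = flip_augment(tiny_records[:1])
        orig, vf, hf = out
        assert np.array_equal(np.flip(vf.image, 0), orig.image)
        assert np.array_equal(np.flip(vf.mask, 0), orig.mask)
        assert np.array_equal(np.flip(hf.image, 1), orig.image)
        assert vf.provenance == "vflip" and hf.provenance == "hflip"
        assert vf.root_id == orig.id

    def test_flip_commutes_with_binarization(self):
        rng = np.random.default_rng(1)
        raw = (rng.random((12, 12)) * 255).astype(np.uint8)
        a = np.flip((raw > 0).astype(np.uint8), 0)
        b = (np.flip(raw, 0) > 0).astype(np.uint8)
        assert np.array_equal(a, b)


class TestTranslateAugment:
    def test_exact_target_counts(self, tiny_records):
        flipped = flip_augment(tiny_records)
        out = translate_augment(flipped, 3000, max_offset=8, seed=0)
        assert len(out) == 3000
        assert out[:60] == flipped  # originals lead, untouched

    def test_no_translation_when_target_equals_input(self, tiny_records):
        out = translate_augment(tiny_records, len(tiny_records),
                                max_offset=8, seed=0)
        assert out == tiny_records

    def test_seed_reproducibility(self, tiny_records):
        a = translate_augment(tiny_records, 100, max_offset=8, seed=42)
        b = translate_augment(tiny_records, 100, max_offset=8, seed=42)
        assert [r.offset for r in a] == [r.offset for r in b]
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))

    def test_offset_applied_identically_to_image_and_mask(self, tiny_records):
        out = translate_augment(tiny_records[:1], 5, max_offset=6, seed=3)
        for rec in out[1:]:
            dx, dy = rec.offset
            src = tiny_records[0]
            # undo the inherited flip if any, then compare to raw translation
            img, msk = rec.image, rec.mask
            timg = _translate(src.image, dx, dy)
            tmsk = _translate(src.mask, dx, dy)
            match = any(
                np.array_equal(img, f(timg)) and np.array_equal(msk, f(tmsk))
                for f in (lambda a: a, lambda a: np.flip(a, 0),
                          lambda a: np.flip(a, 1)))
            assert match
            assert rec.provenance == "translated"

    def test_excessive_offset_rejected(self, tiny_records):
        with pytest.raises(ConfigurationError, match="max_offset"):
            translate_augment(tiny_records, 100, max_offset=24, seed=0)

    def test_translate_commutes_with_binarization(self):
        rng = np.random.default_rng(2)
        raw = (rng.random((12, 12)) * 255).astype(np.uint8)
        a = _translate((raw > 0).astype(np.uint8), 3, -2)
        b = (_translate(raw, 3, -2) > 0).astype(np.uint8)
        assert np.array_equal(a, b)


class TestDatasetProfiles:
    @pytest.mark.parametrize("profile,n_train,target", [
        ("drive", 20, 3000), ("chase-db1", 20, 1500), ("stare", 19, 1300)])
    def test_published_augmentation_totals(self, profile, n_train, target):
        rng = np.random.default_rng(0)
        recs = [SampleRecord(id=f"x{i:02d}",
                             image=rng.random((24, 24, 3)).astype(np.float32),
                             mask=(rng.random((24, 24)) > 0.9).astype(np.uint8))
                for i in range(n_train)]
        out = translate_augment(flip_augment(recs),
                                DATASET_PROFILES[profile]["augment_target"],
                                max_offset=8, seed=0)
        assert len(flip_augment(recs)) == 3 * n_train
        assert len(out) == target


class TestSplits:
    def test_leave_one_out_partition(self, tiny_records):
        folds = make_splits(tiny_records, SplitProtocol("leave_one_out"))
        assert len(folds) == 20
        tested = [test_ids[0] for _, test_ids in folds]
        assert sorted(tested) == sorted(r.id for r in tiny_records)
        for train_ids, test_ids in folds:
            assert len(train_ids) == 19 and len(test_ids) == 1
            assert not set(train_ids) & set(test_ids)

    def test_fixed_split_drive_profile(self, tiny_records):
        extra = [SampleRecord(id=f"im{i:02d}", image=r.image, mask=r.mask)
                 for i, r in enumerate(tiny_records, start=20)]
        folds = make_splits(tiny_records + extra,
                            SplitProtocol("fixed_split", 20, 20))
        assert len(folds) == 1
        train_ids, test_ids = folds[0]
        assert len(train_ids) == 20 and len(test_ids) == 20
        assert train_ids == sorted(train_ids)

    def test_size_conflict_rejected(self, tiny_records):
        with pytest.raises(ValidationError):
            make_splits(tiny_records, SplitProtocol("fixed_split", 20, 20))

    def test_leakage_freedom_via_lineage(self, tiny_records):
        folds = make_splits(tiny_records, SplitProtocol("leave_one_out"))
        train_ids, test_ids = folds[0]
        train_recs = [r for r in tiny_records if r.id in train_ids]
        augmented = translate_augment(flip_augment(train_recs), 200,
                                      max_offset=8, seed=0)
        assert not {r.root_id for r in augmented} & set(test_ids)


class TestManifestRoundtrip:
    def test_csv_roundtrip_preserves_fields(self, tiny_records, tmp_path):
        recs = flip_augment(tiny_records[:2])
        recs = translate_augment(recs, 8, max_offset=8, seed=1)
        written = [write_pair(r, tmp_path / "imgs") for r in recs]
        save_manifest(written, tmp_path / "manifest.csv")
        loaded = load_manifest(tmp_path / "manifest.csv")
        assert [r.id for r in loaded] == [r.id for r in written]
        assert [r.provenance for r in loaded] == [r.provenance for r in written]
        assert [r.offset for r in loaded] == [r.offset for r in written]
        assert [r.root_id for r in loaded] == [r.root_id for r in written]
        # masks survive the {0,255} PNG roundtrip exactly
        for a, b in zip(loaded, written):
            assert np.array_equal(a.mask, b.mask)
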