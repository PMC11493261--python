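"""Dataset generation, folder I/O round-trips, and augmentation geometry."""

import numpy as np
import pytest
from PIL import Image

from advdefend import (AugmentConfig, CLASS_NAMES, ImageBatch,
                       SyntheticConfig, augment, load_image_folder,
                       make_synthetic_dataset, write_attack_hierarchy)
from advdefend.data import SPLIT_NAMES, write_dataset_folder
from advdefend.errors import DataError


# ---------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------

class TestSyntheticGenerator:
    def test_same_config_is_bit_identical(self):
        cfg = SyntheticConfig(
            n_per_class_per_split={"train": 4, "test": 4, "validation": 4},
            image_size=16, seed=11)
        a = make_synthetic_dataset(cfg)
        b = make_synthetic_dataset(cfg)
        for split in SPLIT_NAMES:
            assert np.array_equal(a.split(split).pixels, b.split(split).pixels)
            assert a.split(split).ids == b.split(split).ids

    def test_different_seed_changes_pixels(self):
        small = dict(n_per_class_per_split={"train": 4, "test": 4,
                                            "validation": 4}, image_size=16)
        a = make_synthetic_dataset(SyntheticConfig(seed=1, **small))
        b = make_synthetic_dataset(SyntheticConfig(seed=2, **small))
        assert not np.array_equal(a.train.pixels, b.train.pixels)

    def test_zero_noise_images_differ_only_by_jitter(self):
        """With noise_sd=0 the per-image variation is the documented motif
        jitter: images of one class differ, but smoothly (no pixel noise)."""
        ds = make_synthetic_dataset(SyntheticConfig(
            n_per_class_per_split={"train": 6, "test": 1, "validation": 1},
            image_size=32, noise_sd=0.0, seed=3))
        normal = ds.train.select_class(1).pixels
        # normal-class jitter is a global brightness shift: after removing
        # the per-image mean all images collapse to the same background
        centered = normal - normal.mean(axis=(1, 2, 3), keepdims=True)
        spread = np.ptp(centered, axis=0).max()
        assert 0 < np.ptp(normal, axis=0).max()  # images do differ
        assert spread < 1e-5                     # ...only by the documented shift
        # blob class: variation is smooth (position/size), not iid noise —
        # neighbouring-pixel differences stay far below the image contrast
        blob = ds.train.select_class(0).pixels
        lap = np.abs(np.diff(blob, axis=1)).max()
        assert lap < 0.2

    def test_class_mean_images_are_pairwise_distinct(self):
        """Brute-force L2 distance between class means, per split."""
        ds = make_synthetic_dataset(SyntheticConfig(seed=7))  # defaults
        batch = ds.train
        means = [batch.select_class(c).pixels.mean(axis=0) for c in range(3)]
        for a in range(3):
            for b in range(a + 1, 3):
                # explicit pixel loop as the independent distance oracle
                acc = 0.0
                da, db = means[a][..., 0], means[b][..., 0]
                for r in range(da.shape[0]):
                    for c in range(da.shape[1]):
                        acc += (da[r, c] - db[r, c]) ** 2
                assert np.sqrt(acc) > 1.0
                assert np.sqrt(acc) == pytest.approx(
                    float(np.linalg.norm(means[a] - means[b])), rel=1e-6)

    def test_invalid_configs_rejected(self):
        with pytest.raises(DataError):
            SyntheticConfig(image_size=8)
        with pytest.raises(DataError):
            SyntheticConfig(noise_sd=-0.1)
        with pytest.raises(DataError):
            SyntheticConfig(n_per_class_per_split={"train": 0, "test": 1,
                                                   "validation": 1})

    def test_batch_invariants(self, tiny_dataset):
        for split in SPLIT_NAMES:
            b = tiny_dataset.split(split)
            assert b.pixels.min() >= 0.0 and b.pixels.max() <= 1.0
            assert set(np.unique(b.labels)) <= {0, 1, 2}
            assert len(b.labels) == len(b) == len(b.ids)


# ---------------------------------------------------------------------
# folder I/O
# ---------------------------------------------------------------------

class TestFolderIO:
    def test_round_trip_counts_labels_and_pixels(self, tiny_dataset, tmp_path):
        write_dataset_folder(tiny_dataset, tmp_path / "ds")
        loaded = load_image_folder(tmp_path / "ds", image_size=16)
        for split in SPLIT_NAMES:
            orig, got = tiny_dataset.split(split), loaded.split(split)
            assert len(got) == len(orig)
            assert np.array_equal(np.sort(got.labels), np.sort(orig.labels))
            # PNG is lossless: pixels agree up to 8-bit quantization
            order_o = np.argsort(orig.ids)
            order_g = np.argsort(got.ids)
            assert np.abs(got.pixels[order_g]
                          - orig.pixels[order_o]).max() <= 1 / 255

    def test_label_order_is_sorted_class_names(self, tmp_path):
        for split in SPLIT_NAMES:
            for cls in CLASS_NAMES:
                d = tmp_path / split / cls
                d.mkdir(parents=True)
                Image.new("L", (16, 16), color=128).save(d / "img.png")
        ds = load_image_folder(tmp_path, image_size=16)
        assert list(ds.train.labels) == [0, 1, 2]
        assert [i.split("/")[1] for i in ds.train.ids] == list(CLASS_NAMES)

    def test_solid_black_jpeg_loads_as_zeros(self, tmp_path):
        for split in SPLIT_NAMES:
            for cls in CLASS_NAMES:
                d = tmp_path / split / cls
                d.mkdir(parents=True)
                Image.new("L", (16, 16), color=0).save(d / "black.jpeg")
        ds = load_image_folder(tmp_path, image_size=16)
        assert ds.test.pixels.max() == 0.0

    def test_published_test_split_counts(self, tmp_path):
        """Synthetic stand-ins at the published test-split sizes:
        242 bacterial + 234 normal + 140 viral = 616 images."""
        counts = {"bacterial": 242, "normal": 234, "viral": 140}
        for split in SPLIT_NAMES:
            for cls in CLASS_NAMES:
                d = tmp_path / split / cls
                d.mkdir(parents=True)
                n = counts[cls] if split == "test" else 1
                for i in range(n):
                    Image.new("L", (16, 16), color=90).save(d / f"{i}.png")
        ds = load_image_folder(tmp_path, image_size=16)
        assert len(ds.test) == 616
        assert int((ds.test.labels == 0).sum()) == 242
        assert int((ds.test.labels == 2).sum()) == 140

    def test_missing_directories_are_named(self, tmp_path):
        with pytest.raises(DataError, match="train"):
            load_image_folder(tmp_path / "nope", image_size=16)
        (tmp_path / "train" / "bacterial").mkdir(parents=True)
        with pytest.raises(DataError, match="normal"):
            load_image_folder(tmp_path, image_size=16)

    def test_undecodable_file_is_named(self, tmp_path):
        for split in SPLIT_NAMES:
            for cls in CLASS_NAMES:
                d = tmp_path / split / cls
                d.mkdir(parents=True)
                Image.new("L", (16, 16)).save(d / "ok.png")
        bad = tmp_path / "train" / "viral" / "broken.png"
        bad.write_bytes(b"not an image")
        with pytest.raises(DataError, match="broken.png"):
            load_image_folder(tmp_path, image_size=16)


# ---------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------

class TestAugment:
    def test_identity_config_returns_input(self, tiny_dataset):
        cfg = AugmentConfig(rotation_deg=0, scale_range=(1, 1),
                            translate_frac=0, seed=0)
        out = augment(tiny_dataset.train, cfg)
        assert np.allclose(out.pixels, tiny_dataset.train.pixels, atol=1e-6)

    def test_labels_and_ids_unchanged(self, tiny_dataset):
        out = augment(tiny_dataset.train, AugmentConfig(seed=5))
        assert np.array_equal(out.labels, tiny_dataset.train.labels)
        assert out.ids == tiny_dataset.train.ids
        assert out.pixels.min() >= 0 and out.pixels.max() <= 1

    def test_pure_translation_moves_pixel_to_predicted_location(self):
        size = 17
        img = np.zeros((1, size, size, 1), np.float32)
        img[0, 8, 8, 0] = 1.0
        batch = ImageBatch(img, [0], ["x"])
        # translate_frac chosen so the drawn shift rounds to whole pixels:
        # with a fixed seed we recover the drawn (ty, tx) and check directly
        cfg = AugmentConfig(rotation_deg=0, scale_range=(1, 1),
                            translate_frac=0.3, seed=123)
        rng = np.random.default_rng(123)
        rng.uniform(0, 0)  # rotation draw
        rng = np.random.default_rng(123)
        angle = rng.uniform(0, 0)
        scale = rng.uniform(1, 1)
        ty, tx = rng.uniform(-0.3, 0.3, size=2) * size
        out = augment(batch, cfg)
        peak = np.unravel_index(out.pixels[0, :, :, 0].argmax(), (size, size))
        assert abs(peak[0] - (8 + ty)) <= 1.0
        assert abs(peak[1] - (8 + tx)) <= 1.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(DataError):
            AugmentConfig(scale_range=(1.2, 0.8))
        with pytest.raises(DataError):
            AugmentConfig(translate_frac=0.7)


# ---------------------------------------------------------------------
# attack hierarchy writer (counting logic; attack content tested elsewhere)
# ---------------------------------------------------------------------

class TestWriteHierarchy:
    def _one_image_map(self):
        img = np.full((1, 16, 16, 1), 0.5, np.float32)
        return {("fgsm", 0.1, "train", "normal"):
                ImageBatch(img, [1], ["train/normal/0000"])}

    def test_single_image_manifest(self, tmp_path):
        manifest = write_attack_hierarchy(self._one_image_map(), tmp_path)
        assert manifest["total"] == 1
        assert manifest["folders"] == {"fgsm/eps_0.1": 1}
        assert (tmp_path / "attacks" / "fgsm" / "eps_0.1" / "train" /
                "normal" / "train_normal_0000.png").exists()

    def test_refuses_nonempty_target_without_overwrite(self, tmp_path):
        write_attack_hierarchy(self._one_image_map(), tmp_path)
        with pytest.raises(DataError, match="overwrite"):
            write_attack_hierarchy(self._one_image_map(), tmp_path)
        write_attack_hierarchy(self._one_image_map(), tmp_path, overwrite=True)

    def test_round_trip_through_loader(self, tiny_dataset, tmp_path):
        adv = {}
        for split in SPLIT_NAMES:
            for label, cls in enumerate(CLASS_NAMES):
                adv[("pgd", 0.05, split, cls)] = \
                    tiny_dataset.split(split).select_class(label)
        manifest = write_attack_hierarchy(adv, tmp_path)
        assert manifest["total"] == 9 * 12
        loaded = load_image_folder(tmp_path / "attacks" / "pgd" / "eps_0.05",
                                   image_size=16)
        for split in SPLIT_NAMES:
            orig, got = tiny_dataset.split(split), loaded.split(split)
            assert len(got) == len(orig)
            order_o, order_g = np.argsort(orig.ids), np.argsort(got.ids)
            assert np.abs(got.pixels[order_g]
                          - orig.pixels[order_o]).max() <= 1 / 255
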