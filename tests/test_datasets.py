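"""Dataset loading, splitting, mixing, and fixture-generation contracts."""

import numpy as np
import pytest
from PIL import Image

from dlbcnet.datasets import (LabeledImageSet, SplitSpec,
                              assemble_mixed_dataset, load_image_dataset,
                              make_gaussian_features,
                              make_synthetic_cell_images, split_dataset)


def _write_tree(root, counts, size=(20, 20)):
    rng = np.random.default_rng(1)
    for cls, n in counts.items():
        (root / cls).mkdir(parents=True)
        for i in range(n):
            arr = rng.integers(0, 256, size=size + (3,), dtype=np.uint8)
            Image.fromarray(arr).save(root / cls / f"img_{i:03d}.png")


class TestLoadImageDataset:
    def test_counts_and_labels(self, tmp_path):
        _write_tree(tmp_path, {"a": 3, "b": 3})
        data = load_image_dataset(tmp_path, image_size=(16, 16))
        assert len(data) == 6
        assert list(data.labels) == [0, 0, 0, 1, 1, 1]
        assert all(im.shape == (16, 16, 3) for im in data.images)

    def test_deterministic_ordering(self, tmp_path):
        _write_tree(tmp_path, {"a": 4, "b": 2})
        d1 = load_image_dataset(tmp_path, image_size=(16, 16))
        d2 = load_image_dataset(tmp_path, image_size=(16, 16))
        assert np.array_equal(d1.labels, d2.labels)
        assert all(np.array_equal(x, y) for x, y in zip(d1.images, d2.images))

    def test_empty_class_errors_with_name(self, tmp_path):
        _write_tree(tmp_path, {"a": 2})
        (tmp_path / "empty_cls").mkdir()
        with pytest.raises(ValueError, match="empty_cls"):
            load_image_dataset(tmp_path, image_size=(16, 16))

    def test_missing_class_dir_errors_with_name(self, tmp_path):
        _write_tree(tmp_path, {"a": 2})
        with pytest.raises(FileNotFoundError, match="ghost"):
            load_image_dataset(tmp_path, class_names=["a", "ghost"],
                               image_size=(16, 16))

    def test_unreadable_file_skipped(self, tmp_path):
        _write_tree(tmp_path, {"a": 2, "b": 2})
        (tmp_path / "a" / "broken.png").write_bytes(b"not an image")
        data = load_image_dataset(tmp_path, image_size=(16, 16))
        assert len(data) == 4


class TestSplitDataset:
    def test_stratified_fraction(self):
        data = make_synthetic_cell_images(100, 2, (16, 16), seed=0)
        tr, te = split_dataset(data, SplitSpec(train_fraction=0.7, seed=0))
        assert list(tr.class_counts()) == [70, 70]
        assert list(te.class_counts()) == [30, 30]

    def test_explicit_counts_honored(self):
        # a 3120-image class split exactly into 2184 train / 936 test
        images = [np.zeros((16, 16, 3), dtype=np.uint8)] * 3120
        data = LabeledImageSet(images, np.zeros(3120, dtype=int), ["eosinophil"])
        tr, te = split_dataset(
            data, SplitSpec(per_class_counts={0: (2184, 936)}, seed=0))
        assert len(tr) == 2184 and len(te) == 936

    def test_seed_determinism_and_conservation(self, cell_images):
        s = SplitSpec(train_fraction=0.6, seed=11)
        tr1, te1 = split_dataset(cell_images, s)
        tr2, te2 = split_dataset(cell_images, s)
        assert np.array_equal(tr1.labels, tr2.labels)
        assert all(np.array_equal(a, b) for a, b in zip(tr1.images, tr2.images))
        # split conserves per-class counts exactly
        assert np.array_equal(tr1.class_counts() + te1.class_counts(),
                              cell_images.class_counts())

    def test_tiny_class_errors(self):
        data = LabeledImageSet([np.zeros((16, 16, 3), dtype=np.uint8)],
                               np.array([0]), ["only"])
        with pytest.raises(ValueError, match="fewer than 2"):
            split_dataset(data, SplitSpec(seed=0))


class TestAssembleMixedDataset:
    def test_reference_composition_counts(self):
        blank = np.zeros((8, 8, 3), dtype=np.uint8)
        train = LabeledImageSet([blank] * 2184, np.zeros(2184, dtype=int),
                                ["eosinophil"])
        synth = LabeledImageSet([blank] * 3000, np.zeros(3000, dtype=int),
                                ["eosinophil"], provenance=["synthetic"] * 3000)
        mixed = assemble_mixed_dataset(train, synth)
        assert len(mixed) == 5184
        assert mixed.provenance.count("synthetic") == 3000

    def test_empty_synthetic_is_identity(self, cell_images):
        empty = LabeledImageSet([], np.array([], dtype=int),
                                list(cell_images.class_names))
        assert assemble_mixed_dataset(cell_images, empty) is cell_images

    def test_class_mismatch_errors(self, cell_images):
        blank = np.zeros((8, 8, 3), dtype=np.uint8)
        other = LabeledImageSet([blank], np.array([0]), ["stranger"],
                                provenance=["synthetic"])
        with pytest.raises(ValueError, match="class-name"):
            assemble_mixed_dataset(cell_images, other)

    def test_original_provenance_rejected(self, cell_images):
        blank = np.zeros((8, 8, 3), dtype=np.uint8)
        fake = LabeledImageSet([blank], np.array([0]),
                               list(cell_images.class_names))
        with pytest.raises(ValueError, match="synthetic"):
            assemble_mixed_dataset(cell_images, fake)


class TestSyntheticCellImages:
    def test_counts_and_determinism(self):
        d1 = make_synthetic_cell_images(50, 4, (32, 32), seed=3)
        d2 = make_synthetic_cell_images(50, 4, (32, 32), seed=3)
        assert len(d1) == 200
        assert list(d1.class_counts()) == [50] * 4
        assert all(np.array_equal(a, b) for a, b in zip(d1.images, d2.images))

    def test_too_small_image_errors(self):
        with pytest.raises(ValueError, match="16x16"):
            make_synthetic_cell_images(5, 2, (8, 8), seed=0)

    def test_classes_separable_by_mean_color(self):
        """A mean-color nearest-centroid classifier must exceed 0.90 held-out
        accuracy: the fixture classes are separable by trivial statistics."""
        data = make_synthetic_cell_images(40, 4, (32, 32), seed=5)
        feats = np.array([im.mean(axis=(0, 1)) for im in data.images])
        y = data.labels
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        half = len(y) // 2
        tr, te = idx[:half], idx[half:]
        centroids = np.array([feats[tr][y[tr] == k].mean(axis=0) for k in range(4)])
        pred = np.argmin(((feats[te][:, None, :] - centroids) ** 2).sum(-1), axis=1)
        assert (pred == y[te]).mean() > 0.90


class TestGaussianFeatures:
    def test_determinism_and_shapes(self):
        x1, y1 = make_gaussian_features(30, 3, 5, 4.0, seed=9)
        x2, y2 = make_gaussian_features(30, 3, 5, 4.0, seed=9)
        assert x1.shape == (90, 5)
        assert np.array_equal(x1, x2) and np.array_equal(y1, y2)

    def test_zero_separation_indistinguishable(self):
        """With zero separation any linear classifier stays near chance."""
        x, y = make_gaussian_features(200, 4, 8, 0.0, seed=1)
        from dlbcnet.rnn import one_hot
        B, *_ = np.linalg.lstsq(np.hstack([x, np.ones((len(x), 1))]),
                                one_hot(y, 4), rcond=None)
        xt, yt = make_gaussian_features(200, 4, 8, 0.0, seed=2)
        pred = np.argmax(np.hstack([xt, np.ones((len(xt), 1))]) @ B, axis=1)
        assert abs((pred == yt).mean() - 0.25) < 0.1

    def test_high_separation_linearly_separable(self):
        """separation=10 clouds: least-squares classifier >= 0.99 held out."""
        x, y = make_gaussian_features(200, 4, 8, 10.0, seed=1)
        from dlbcnet.rnn import one_hot
        B, *_ = np.linalg.lstsq(x, one_hot(y, 4), rcond=None)
        xt, yt = make_gaussian_features(100, 4, 8, 10.0, seed=3)
        assert (np.argmax(xt @ B, axis=1) == yt).mean() >= 0.99


def test_write_tree_roundtrip(tmp_path, cell_images):
    cell_images.write_tree(tmp_path / "tree", split="train")
    loaded = load_image_dataset(tmp_path / "tree", image_size=(32, 32))
    assert len(loaded) == len(cell_images)
    assert (tmp_path / "tree" / "manifest.csv").exists()
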