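"""Image datasets, stratified splits, mixed-set assembly, and synthetic fixtures.

A labelled image collection moves between three stages: per-class GAN
augmentation, backbone fine-tuning, and evaluation.  Training sets may mix
original and synthetic images; test sets only ever contain originals, and the
provenance tag on every image enforces that contract.

The fixture generators (`make_synthetic_cell_images`,
`make_gaussian_features`) produce class-separable stand-ins for real
microscopy data so that every downstream stage is testable without any
download: colored elliptical "nucleus" blobs on a textured background for the
image path, and isotropic Gaussian clouds on orthogonal-ish directions for
the feature path.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


@dataclass
class LabeledImageSet:
    """RGB images with integer class labels and per-image provenance."""

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.provenance:
            self.provenance = ["original"] * len(self.images)
        self.validate()

    def validate(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if len(self.provenance) != len(self.images):
            raise ValueError("provenance and images length mismatch")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("label outside [0, n_classes)")
        for im in self.images:
            if im.ndim != 3 or im.shape[2] != 3:
                raise ValueError("every image must be HxWx3")
            if im.min() < 0 or im.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
        bad = set(self.provenance) - {"original", "synthetic"}
        if bad:
            raise ValueError(f"unknown provenance tags: {bad}")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "LabeledImageSet":
        idx = np.asarray(idx, dtype=int)
        return LabeledImageSet(
            images=[self.images[i] for i in idx],
            labels=self.labels[idx],
            class_names=list(self.class_names),
            provenance=[self.provenance[i] for i in idx],
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(self.class_names))

    def as_array(self, dtype=np.float64) -> np.ndarray:
        """Stack into (N, H, W, 3); requires uniform image size."""
        return np.stack(self.images).astype(dtype)

    def write_tree(self, root: Path, manifest: str | None = "manifest.csv",
                   split: str = "") -> None:
        """Write class-per-subdirectory PNGs plus a provenance manifest CSV."""
        root = Path(root)
        rows = []
        counters: dict[int, int] = {}
        for i, (im, lab, prov) in enumerate(zip(self.images, self.labels, self.provenance)):
            cls = self.class_names[lab]
            (root / cls).mkdir(parents=True, exist_ok=True)
            k = counters.get(lab, 0)
            counters[lab] = k + 1
            path = root / cls / f"{prov}_{k:05d}.png"
            Image.fromarray(im.astype(np.uint8)).save(path)
            rows.append([str(path.relative_to(root)), int(lab), prov, split])
        if manifest:
            with open(root / manifest, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["path", "label", "provenance", "split"])
                w.writerows(rows)


@dataclass
class SplitSpec:
    """Stratified train/test split specification.

    Either a global ``train_fraction`` or explicit per-class
    ``(n_train, n_test)`` counts; the shuffle before splitting is seeded.
    """

    train_fraction: float = 0.7
    per_class_counts: dict[int, tuple[int, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def load_image_dataset(root_dir, class_names: list[str] | None = None,
                       image_size: tuple[int, int] = (224, 224)) -> LabeledImageSet:
    """Load a class-per-subdirectory image tree, resized with bilinear interpolation.

    Class order is the sorted subdirectory order unless ``class_names`` is
    given explicitly; files are visited in lexicographic path order so two
    loads of the same tree are identical.
    """
    root = Path(root_dir)
    if class_names is None:
        class_names = sorted(p.name for p in root.iterdir() if p.is_dir())
        if not class_names:
            raise ValueError(f"no class subdirectories under {root}")
    images, labels = [], []
    for k, cls in enumerate(class_names):
        cdir = root / cls
        if not cdir.is_dir():
            raise FileNotFoundError(f"missing class subdirectory for class '{cls}'")
        n_before = len(images)
        for path in sorted(cdir.iterdir()):
            if path.suffix.lower() not in _IMAGE_EXTENSIONS:
                continue
            try:
                with Image.open(path) as im:
                    im = im.convert("RGB").resize(
                        (image_size[1], image_size[0]), Image.BILINEAR)
                    images.append(np.asarray(im, dtype=np.uint8))
                    labels.append(k)
            except Exception as exc:  # unreadable file: skip, keep loading
                logger.warning("skipping unreadable image %s: %s", path, exc)
        if len(images) == n_before:
            raise ValueError(f"class '{cls}' contains no readable images")
    return LabeledImageSet(images, np.array(labels), list(class_names))


def split_dataset(data: LabeledImageSet, spec: SplitSpec) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Seeded, stratified partition into train and test subsets."""
    rng = np.random.default_rng(spec.seed)
    train_idx, test_idx = [], []
    for k in range(len(data.class_names)):
        idx = np.flatnonzero(data.labels == k)
        if len(idx) < 2:
            raise ValueError(f"class '{data.class_names[k]}' has fewer than 2 images")
        idx = rng.permutation(idx)
        if spec.per_class_counts is not None and k in spec.per_class_counts:
            n_tr, n_te = spec.per_class_counts[k]
            if n_tr + n_te > len(idx):
                raise ValueError(
                    f"requested {n_tr}+{n_te} images for class "
                    f"'{data.class_names[k]}' but only {len(idx)} exist")
        else:
            n_tr = int(round(spec.train_fraction * len(idx)))
            n_tr = min(max(n_tr, 1), len(idx) - 1)
            n_te = len(idx) - n_tr
        train_idx.extend(idx[:n_tr])
        test_idx.extend(idx[n_tr : n_tr + n_te])
    return data.subset(train_idx), data.subset(test_idx)


def assemble_mixed_dataset(train: LabeledImageSet, synthetic: LabeledImageSet) -> LabeledImageSet:
    """Append synthetic images to a training split; never applied to test sets."""
    if len(synthetic) == 0:
        return train
    if synthetic.class_names != train.class_names:
        raise ValueError("class-name tables of train and synthetic sets differ")
    if any(p != "synthetic" for p in synthetic.provenance):
        raise ValueError("every augmentation image must carry provenance='synthetic'")
    return LabeledImageSet(
        images=train.images + synthetic.images,
        labels=np.concatenate([train.labels, synthetic.labels]),
        class_names=list(train.class_names),
        provenance=train.provenance + synthetic.provenance,
    )


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb)


def make_synthetic_cell_images(n_per_class: int, n_classes: int,
                               image_size: tuple[int, int] = (64, 64),
                               seed: int = 0) -> LabeledImageSet:
    """Render class-separable cell-like fixture images.

    Class ``k`` gets a pale textured background and ``k+1`` elliptical nucleus
    blobs in a class-specific hue with jittered size/position, so classes are
    distinguishable by simple color and shape statistics.  Bit-reproducible
    for a fixed seed.
    """
    if n_per_class < 1 or n_classes < 2:
        raise ValueError("need n_per_class >= 1 and n_classes >= 2")
    h, w = image_size
    if h < 16 or w < 16:
        raise ValueError(f"image_size must be at least 16x16, got {image_size}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    images, labels = [], []
    for k in range(n_classes):
        hue = k / n_classes
        blob_rgb = _hsv_to_rgb(hue, 0.85, 0.75) * 255
        bg_rgb = _hsv_to_rgb(hue, 0.12, 0.92) * 255
        for _ in range(n_per_class):
            img = bg_rgb[None, None, :] + rng.normal(0, 8, size=(h, w, 3))
            for _blob in range(k + 1):
                cy = rng.uniform(0.2, 0.8) * h
                cx = rng.uniform(0.2, 0.8) * w
                base = (0.10 + 0.02 * k) * min(h, w)
                ay = base * rng.uniform(0.8, 1.2)
                ax = base * rng.uniform(0.8, 1.2)
                mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
                shade = blob_rgb * rng.uniform(0.9, 1.1)
                img[mask] = 0.15 * img[mask] + 0.85 * shade
            images.append(np.clip(img, 0, 255).astype(np.uint8))
            labels.append(k)
    names = [f"class_{k}" for k in range(n_classes)]
    return LabeledImageSet(images, np.array(labels), names,
                           provenance=["original"] * len(images))


def make_gaussian_features(n_per_class: int, n_classes: int, dim: int,
                           separation: float, seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic unit-variance Gaussian clouds at ``separation * u_k``.

    The class directions ``u_k`` are rows of a fixed orthonormal-ish frame
    (QR of a deterministically seeded matrix, independent of ``seed``), so
    ``separation`` directly controls between-class distance in units of the
    within-class standard deviation.
    """
    if dim < 1 or separation < 0:
        raise ValueError("need dim >= 1 and separation >= 0")
    if n_per_class < 1 or n_classes < 2:
        raise ValueError("need n_per_class >= 1 and n_classes >= 2")
    frame_rng = np.random.default_rng(987654321)
    a = frame_rng.normal(size=(max(dim, n_classes), dim))
    q, _ = np.linalg.qr(a.T if dim >= n_classes else a)
    if dim >= n_classes:
        directions = q.T[:n_classes]
    else:  # more classes than dimensions: normalized rows, only "orthogonal-ish"
        directions = a[:n_classes] / np.linalg.norm(a[:n_classes], axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for k in range(n_classes):
        feats.append(separation * directions[k] + rng.normal(size=(n_per_class, dim)))
        labels.extend([k] * n_per_class)
    return np.vstack(feats), np.array(labels)
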