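"""Frozen-trunk transfer-learning feature extractor with a six-layer head.

A pre-trained (or, for desk-scale work, randomly initialized) convolutional
trunk ending in a global pooling layer is kept frozen.  Six layers are
appended and trained on the target data:

    FC128 -> ReLU -> BN -> FC4 -> Softmax -> Classification

The FC128/ReLU/BN "buffer" layers smooth the dimensionality reduction from
the wide pooled trunk output down to the class count.  After fine-tuning, the
last five head layers are discarded and the 128-dimensional FC128 activation
(pre-ReLU) is tapped as the feature representation fed to the downstream
randomized-network classifiers.

Fine-tuning minimizes categorical cross-entropy with Adam over the head
parameters only; frozen trunk weights are bit-identical before and after.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .datasets import LabeledImageSet

logger = logging.getLogger(__name__)

HEAD_LAYER_NAMES = ["FC128", "ReLU", "BN", "FC4", "Softmax", "Classification"]


class ClassificationLayer(nn.Layer):
    """Decision stage: identity on probabilities; argmax lives in `predict`."""

    def forward(self, x, train=False):
        return x

    def backward(self, dout):
        return dout


class TinyConvTrunk:
    """Small random convolutional trunk with a pooled-vector endpoint.

    A frozen, randomly initialized stand-in for a large pre-trained trunk:
    two strided conv/ReLU stages followed by global average pooling.  Random
    convolutions still produce class-informative color/texture summaries of
    the fixture images, which is all desk-scale testing needs.
    """

    def __init__(self, out_dim: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.net = nn.Sequential([
            nn.Conv2d(3, 16, 3, rng, stride=2),
            nn.ReLU(),
            nn.Conv2d(16, out_dim, 3, rng, stride=2),
            nn.ReLU(),
        ])
        self.out_dim = out_dim
        self.normalization = None  # plain [0,1] pixel scaling

    def forward(self, x_nchw: np.ndarray) -> np.ndarray:
        h = self.net.forward(x_nchw, train=False)
        return h.mean(axis=(2, 3))  # global average pool -> (N, out_dim)

    def state_arrays(self):
        return self.net.state_arrays()


@dataclass
class FeatureMatrix:
    """N x d feature matrix with aligned integer labels."""

    values: np.ndarray
    labels: np.ndarray
    feature_dim: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.feature_dim == 0:
            self.feature_dim = self.values.shape[1]
        if len(self.values) != len(self.labels):
            raise ValueError("values and labels length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.values, columns=[f"f{i}" for i in range(self.feature_dim)])
        df["label"] = self.labels
        df.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        import pandas as pd
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(), labels)


@dataclass
class FinetuneConfig:
    """Head-training hyper-parameters (defaults: batch 10, 1 epoch, lr 1e-4).

    A single epoch at a small learning rate deliberately under-trains the
    head — the trunk features do most of the work and longer schedules
    overfit small medical image sets.
    """

    mini_batch: int = 10
    max_epoch: int = 1
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.mini_batch < 1 or self.max_epoch < 1 or self.learning_rate <= 0:
            raise ValueError("mini_batch, max_epoch, learning_rate must be positive")


class BackboneModel:
    """Frozen trunk + trainable six-layer head."""

    def __init__(self, trunk, num_classes: int = 4, head_seed: int = 0):
        if num_classes < 2:
            raise ValueError("need num_classes >= 2")
        if not hasattr(trunk, "forward") or not hasattr(trunk, "out_dim"):
            raise TypeError("trunk must expose a pooled-vector endpoint "
                            "(forward() -> (N, out_dim))")
        rng = np.random.default_rng(head_seed)
        self.trunk = trunk
        self.num_classes = num_classes
        self.head = nn.Sequential([
            nn.Dense(trunk.out_dim, 128, rng),      # FC128
            nn.ReLU(),                              # ReLU
            nn.BatchNorm(128),                      # BN
            nn.Dense(128, num_classes, rng),        # FC4
            nn.Softmax(),                           # Softmax
            ClassificationLayer(),                  # Classification
        ])
        self.loss_history: list[float] = []

    @property
    def head_layer_names(self) -> list[str]:
        return list(HEAD_LAYER_NAMES)

    @property
    def trainable_parameter_count(self) -> int:
        return sum(p.size for _, _, p in self.head.parameters())

    def _pixels(self, images: LabeledImageSet) -> np.ndarray:
        """uint8 HWC images -> normalized NCHW float batch."""
        x = images.as_array(np.float64) / 255.0
        if getattr(self.trunk, "normalization", None) is not None:
            mean, std = self.trunk.normalization
            x = (x - np.asarray(mean)) / np.asarray(std)
        return x.transpose(0, 3, 1, 2)

    def forward_probs(self, images: LabeledImageSet, train: bool = False) -> np.ndarray:
        feats = self.trunk.forward(self._pixels(images))
        return self.head.forward(feats, train=train)

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"head.{k}": v for k, v in self.head.state_arrays().items()}
        if hasattr(self.trunk, "state_arrays"):
            arrays.update({f"trunk.{k}": v for k, v in self.trunk.state_arrays().items()})
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"num_classes": self.num_classes,
                "head_layers": self.head_layer_names,
                "trunk_out_dim": self.trunk.out_dim,
                "shapes": {k: list(v.shape) for k, v in arrays.items()}}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def build_modified_backbone(base, num_classes: int = 4, head_seed: int = 0) -> BackboneModel:
    """Attach the FC128/ReLU/BN/FC4/Softmax/Classification head to a frozen trunk."""
    return BackboneModel(base, num_classes, head_seed)


def finetune_backbone(model: BackboneModel, train: LabeledImageSet,
                      cfg: FinetuneConfig) -> BackboneModel:
    """Train the head by mini-batch cross-entropy; the trunk never moves.

    Because the trunk is frozen, its pooled features are computed once and
    the optimization runs entirely on the small head.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    labels = train.labels
    if len(np.unique(labels)) < model.num_classes:
        logger.warning("training labels do not cover all %d classes", model.num_classes)
    feats = model.trunk.forward(model._pixels(train))
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.head.parameters(), lr=cfg.learning_rate)
    n = len(train)
    eps = 1e-12
    for epoch in range(cfg.max_epoch):
        order = rng.permutation(n)
        for start in range(0, n, cfg.mini_batch):
            idx = order[start : start + cfg.mini_batch]
            x, y = feats[idx], labels[idx]
            model.head.zero_grads()
            probs = model.head.forward(x, train=True)
            loss = -np.mean(np.log(probs[np.arange(len(idx)), y] + eps))
            dprobs = np.zeros_like(probs)
            dprobs[np.arange(len(idx)), y] = -1.0 / (probs[np.arange(len(idx)), y] + eps) / len(idx)
            model.head.backward(dprobs)
            opt.step()
            model.loss_history.append(float(loss))
            logger.debug("epoch %d batch %d loss %.4f", epoch, start // cfg.mini_batch, loss)
    return model


def extract_features(model: BackboneModel, images: LabeledImageSet) -> FeatureMatrix:
    """Tap the FC128 activation (pre-ReLU): the layer left standing once the
    last five head layers are replaced by the randomized-network classifiers.

    Pure inference: batch statistics are never used, so the same image always
    maps to the same feature row.
    """
    if len(images) == 0:
        raise ValueError("empty image set")
    feats = model.trunk.forward(model._pixels(images))
    fc128 = model.head.layers[0].forward(feats, train=False)
    return FeatureMatrix(fc128, images.labels)
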