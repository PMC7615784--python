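"""Per-class GAN for blood-cell image synthesis (BCGAN).

One generator/discriminator pair is trained per class and used to emit
synthetic images that are mixed into the training split, enlarging small
medical image sets without touching the test data.

The value function is the classic minimax objective

    F(D, G) = E_x[ln D(x)] + E_z[ln(1 - D(G(z)))],

ascended by the discriminator and descended by the generator in alternating
steps.  Architectural choices aimed at small cell-image sets: extra generator
convolution blocks with widths doubling toward the bottleneck, kernel size 5
(large kernels smear out the checkerboard artifacts of naive upsampling),
and batch normalization plus dropout in both networks against overfitting.
The generator upsamples a dense noise projection with nearest-neighbour
x2 / convolution blocks; the discriminator stacks conv / LeakyReLU /
max-pool / BN / dropout blocks with a sigmoid scalar output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from . import nn
from .datasets import LabeledImageSet

logger = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass
class GANConfig:
    noise_dim: int = 100
    image_size: tuple[int, int] = (64, 64)
    gen_blocks: int = 5
    kernel_size: int = 5
    base_filters: int = 16
    dropout_rate: float = 0.3
    leaky_slope: float = 0.2
    mini_batch: int = 10
    learning_rate: float = 1e-4
    T: int = 200                     # training iterations
    S: int = 1                      # discriminator steps per iteration
    seed: int = 0

    def __post_init__(self):
        if min(self.noise_dim, self.gen_blocks, self.base_filters,
               self.mini_batch, self.T, self.S) < 1 or self.learning_rate <= 0:
            raise ValueError("all GANConfig sizes and rates must be positive")
        if self.kernel_size < 4:
            raise ValueError("kernel_size must be >= 4 (checkerboard mitigation)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        h, w = self.image_size
        f = 2 ** self.gen_blocks
        if h % f or w % f or h // f < 1 or w // f < 1:
            nearest = (max(f, round(h / f) * f or f), max(f, round(w / f) * f or f))
            raise ValueError(
                f"image_size {self.image_size} not reachable by {self.gen_blocks} "
                f"x2-upsampling blocks; nearest valid size is {nearest}")


@dataclass
class GANPair:
    generator: nn.Sequential
    discriminator: nn.Sequential
    cfg: GANConfig
    loss_history: list[tuple[float, float]] = field(default_factory=list)


def build_generator(cfg: GANConfig) -> nn.Sequential:
    """Dense noise projection, then gen_blocks upsample/conv/BN/LeakyReLU/dropout
    blocks, finishing with a tanh conv into 3 channels."""
    rng = np.random.default_rng(cfg.seed)
    h0 = cfg.image_size[0] // 2 ** cfg.gen_blocks
    w0 = cfg.image_size[1] // 2 ** cfg.gen_blocks
    widths = [cfg.base_filters * 2 ** (cfg.gen_blocks - 1 - i) for i in range(cfg.gen_blocks)]
    layers: list[nn.Layer] = [
        nn.Dense(cfg.noise_dim, widths[0] * h0 * w0, rng),
        nn.Reshape((widths[0], h0, w0)),
    ]
    prev = widths[0]
    for fdim in widths:
        layers += [
            nn.UpsampleNearest(),
            nn.Conv2d(prev, fdim, cfg.kernel_size, rng),
            nn.BatchNorm(fdim),
            nn.LeakyReLU(cfg.leaky_slope),
            nn.Dropout(cfg.dropout_rate),
        ]
        prev = fdim
    layers += [nn.Conv2d(prev, 3, cfg.kernel_size, rng), nn.Tanh()]
    net = nn.Sequential(layers)
    net.set_rng(np.random.default_rng(np.random.SeedSequence([cfg.seed, 11])))
    return net


def build_discriminator(cfg: GANConfig) -> nn.Sequential:
    """Conv/LeakyReLU/max-pool/BN/dropout blocks and a sigmoid scalar score."""
    rng = np.random.default_rng(cfg.seed + 1)
    h, w = cfg.image_size
    n_blocks = max(1, int(np.log2(min(h, w))) - 2)
    layers: list[nn.Layer] = []
    prev = 3
    for i in range(n_blocks):
        fdim = cfg.base_filters * 2 ** i
        layers += [
            nn.Conv2d(prev, fdim, cfg.kernel_size, rng),
            nn.LeakyReLU(cfg.leaky_slope),
            nn.MaxPool2d(),
            nn.BatchNorm(fdim),
            nn.Dropout(cfg.dropout_rate),
        ]
        prev = fdim
    flat = prev * (h // 2 ** n_blocks) * (w // 2 ** n_blocks)
    layers += [nn.Flatten(), nn.Dense(flat, 1, rng), nn.Sigmoid()]
    net = nn.Sequential(layers)
    net.set_rng(np.random.default_rng(np.random.SeedSequence([cfg.seed, 13])))
    return net


def gan_value(d_real, d_fake) -> float:
    """Empirical minimax value: mean(ln d_real) + mean(ln(1 - d_fake)).

    Scores at exactly 0 or 1 are clamped to [eps, 1-eps] with a warning so
    the logarithms stay finite.
    """
    d_real = np.atleast_1d(np.asarray(d_real, dtype=float))
    d_fake = np.atleast_1d(np.asarray(d_fake, dtype=float))
    if ((d_real <= 0) | (d_real >= 1)).any() or ((d_fake <= 0) | (d_fake >= 1)).any():
        warnings.warn("discriminator score at 0 or 1 clamped to [eps, 1-eps]")
    d_real = np.clip(d_real, _EPS, 1 - _EPS)
    d_fake = np.clip(d_fake, _EPS, 1 - _EPS)
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


def _to_unit_range(images: LabeledImageSet, size: tuple[int, int]) -> np.ndarray:
    """uint8 HWC -> NCHW float in [-1, 1], resized to the GAN resolution."""
    out = []
    for im in images.images:
        if im.shape[:2] != size:
            pil = Image.fromarray(im.astype(np.uint8)).resize((size[1], size[0]),
                                                              Image.BILINEAR)
            im = np.asarray(pil)
        out.append(im.astype(np.float64) / 127.5 - 1.0)
    return np.stack(out).transpose(0, 3, 1, 2)


def train_bcgan(images: LabeledImageSet, cfg: GANConfig) -> GANPair:
    """Alternating adversarial training on a single-class image set.

    Each iteration runs ``S`` discriminator ascent steps on the empirical
    value function (n real and n generated samples), then one generator
    descent step on ``mean(ln(1 - D(G(z))))``.  All randomness — parameter
    init, dropout, noise, batch sampling — derives from ``cfg.seed``.
    """
    if len(images) < cfg.mini_batch:
        raise ValueError(f"need at least mini_batch={cfg.mini_batch} images, "
                         f"got {len(images)}")
    x_real = _to_unit_range(images, cfg.image_size)
    G = build_generator(cfg)
    D = build_discriminator(cfg)
    ss = np.random.SeedSequence([cfg.seed, 7])
    noise_rng, batch_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    opt_d = nn.Adam(D.parameters(), lr=cfg.learning_rate)
    opt_g = nn.Adam(G.parameters(), lr=cfg.learning_rate)
    n = cfg.mini_batch
    history: list[tuple[float, float]] = []
    for t in range(cfg.T):
        d_loss = g_loss = np.nan
        for _ in range(cfg.S):
            z = noise_rng.normal(size=(n, cfg.noise_dim))
            idx = batch_rng.choice(len(x_real), size=n, replace=len(x_real) < n)
            fake = G.forward(z, train=True)
            batch = np.concatenate([x_real[idx], fake])
            s = np.clip(D.forward(batch, train=True)[:, 0], _EPS, 1 - _EPS)
            s_real, s_fake = s[:n], s[n:]
            d_loss = -(np.mean(np.log(s_real)) + np.mean(np.log(1 - s_fake)))
            ds = np.zeros((2 * n, 1))
            ds[:n, 0] = -1.0 / (s_real * n)       # ascend ln D(x)
            ds[n:, 0] = 1.0 / ((1 - s_fake) * n)  # ascend ln(1 - D(G(z)))
            D.zero_grads()
            D.backward(ds)
            opt_d.step()
        # generator step: minimize mean ln(1 - D(G(z)))
        z = noise_rng.normal(size=(n, cfg.noise_dim))
        fake = G.forward(z, train=True)
        s_fake = np.clip(D.forward(fake, train=True)[:, 0], _EPS, 1 - _EPS)
        g_loss = float(np.mean(np.log(1 - s_fake)))
        ds = (-1.0 / ((1 - s_fake) * n))[:, None]
        D.zero_grads()
        G.zero_grads()
        dimg = D.backward(ds)
        G.backward(dimg)
        opt_g.step()  # discriminator grads from this pass are discarded
        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise RuntimeError(f"non-finite GAN loss at iteration {t}: "
                               f"d_loss={d_loss}, g_loss={g_loss}")
        history.append((float(d_loss), float(g_loss)))
        logger.debug("iter %d d_loss %.4f g_loss %.4f", t, d_loss, g_loss)
    return GANPair(G, D, cfg, history)


def sample_images(pair: GANPair, n: int, class_label: int, seed: int,
                  class_names: list[str] | None = None,
                  out_size: tuple[int, int] | None = None) -> LabeledImageSet:
    """Draw n synthetic images from the generator (inference mode).

    Outputs are mapped from [-1, 1] to [0, 255], optionally resized to the
    classifier input resolution, and tagged provenance='synthetic'.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    imgs: list[np.ndarray] = []
    for start in range(0, n, 64):
        z = rng.normal(size=(min(64, n - start), pair.cfg.noise_dim))
        batch = pair.generator.forward(z, train=False)
        batch = np.clip((batch.transpose(0, 2, 3, 1) + 1.0) * 127.5, 0, 255)
        for im in batch.astype(np.uint8):
            if out_size is not None and im.shape[:2] != out_size:
                im = np.asarray(Image.fromarray(im).resize(
                    (out_size[1], out_size[0]), Image.BILINEAR))
            imgs.append(im)
    if class_names is None:
        class_names = [f"class_{k}" for k in range(class_label + 1)]
    return LabeledImageSet(imgs, np.full(n, class_label), class_names,
                           provenance=["synthetic"] * n)


def write_loss_history(pair: GANPair, path) -> None:
    import pandas as pd
    pd.DataFrame(pair.loss_history, columns=["d_loss", "g_loss"]).rename_axis(
        "iteration").to_csv(path, lineterminator="\n")
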