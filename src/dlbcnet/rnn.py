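"""Randomized single-hidden-layer networks trained by pseudo-inverse.

Three variants share the same recipe — draw input-to-hidden weights ``W`` and
biases ``b`` once, uniformly on [-1, 1], keep them fixed, and solve the
output weights in closed form as the minimum-norm least-squares solution of a
linear system against the one-hot label matrix ``Y``:

* ELM  (extreme learning machine):      ``P = H^+ Y`` with ``H = g(XW + b)``.
* RVFL (random vector functional link): direct input-output links, solved on
  the concatenation ``M = [X | H]``.
* SNN  (Schmidt network):               trainable output bias, solved jointly
  on ``[H | 1]`` so predictions are ``HP + e``.

No gradient descent is involved anywhere: the random hidden layer is frozen
and the optimum of the convex output problem is reached by one SVD-based
solve (``numpy.linalg.pinv``), which also guarantees the returned weights
have minimum Frobenius norm among all least-squares minimizers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

ACTIVATIONS = {
    "sigmoid": expit,
    "tanh": np.tanh,
    "relu": lambda x: np.maximum(x, 0.0),
}


@dataclass
class RNNModel:
    """A trained randomized network (fixed random hidden layer, solved output)."""

    variant: str                     # "ELM" | "RVFL" | "SNN"
    W: np.ndarray                    # d x Z random input-to-hidden weights
    b: np.ndarray                    # Z hidden biases
    activation: str
    P: np.ndarray                    # output weights (rows: Z, d+Z, or Z)
    e: np.ndarray | None             # m-vector output bias (SNN only)
    Z: int
    class_count: int
    seed: int
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.variant not in {"ELM", "RVFL", "SNN"}:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not np.all(np.isfinite(self.P)):
            raise ValueError("non-finite output weights")

    @property
    def input_dim(self) -> int:
        return self.W.shape[0]

    def save(self, path) -> None:
        path = Path(path)
        arrays = {"W": self.W, "b": self.b, "P": self.P}
        if self.e is not None:
            arrays["e"] = self.e
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"variant": self.variant, "activation": self.activation,
                "Z": self.Z, "class_count": self.class_count, "seed": self.seed,
                "class_names": self.class_names}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "RNNModel":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as data:
            arrays = {k: data[k] for k in data.files}
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(variant=meta["variant"], W=arrays["W"], b=arrays["b"],
                   activation=meta["activation"], P=arrays["P"],
                   e=arrays.get("e"), Z=meta["Z"],
                   class_count=meta["class_count"], seed=meta["seed"],
                   class_names=meta.get("class_names", []))


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label outside [0, n_classes)")
    Y = np.zeros((len(labels), n_classes))
    Y[np.arange(len(labels)), labels] = 1.0
    return Y


def init_random_layer(d: int, Z: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw the fixed hidden layer: i.i.d. uniform on [-1, 1], seeded."""
    if d < 1 or Z < 1:
        raise ValueError("need d >= 1 and Z >= 1")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(d, Z))
    b = rng.uniform(-1.0, 1.0, size=Z)
    return W, b


def hidden_output(X: np.ndarray, W: np.ndarray, b: np.ndarray,
                  activation: str = "sigmoid") -> np.ndarray:
    """H[i, j] = g(w_j . x_i + b_j)."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN in input features")
    g = ACTIVATIONS[activation]
    return g(X @ W + b)


def _min_norm_solve(M: np.ndarray, Y: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Minimum-norm least-squares solution of M P = Y (optional ridge)."""
    if not np.any(M):
        warnings.warn("degenerate all-zero design matrix; output weights set to 0")
        return np.zeros((M.shape[1], Y.shape[1]))
    if ridge > 0.0:
        mtm = M.T @ M + ridge * np.eye(M.shape[1])
        return np.linalg.solve(mtm, M.T @ Y)
    rcond = np.finfo(M.dtype).eps * max(M.shape)
    return np.linalg.pinv(M, rcond=rcond) @ Y


def _check_xy(X, Y):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    if not np.allclose(Y.sum(axis=1), 1.0) or not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("Y must be one-hot")
    return X, Y


def train_elm(X, Y, Z: int, seed: int, activation: str = "sigmoid",
              ridge: float = 0.0, class_names: list[str] | None = None) -> RNNModel:
    """ELM: P = H^+ Y on the random hidden layer output."""
    X, Y = _check_xy(X, Y)
    W, b = init_random_layer(X.shape[1], Z, seed)
    H = hidden_output(X, W, b, activation)
    P = _min_norm_solve(H, Y, ridge)
    return RNNModel("ELM", W, b, activation, P, None, Z, Y.shape[1], seed,
                    class_names or [])


def train_rvfl(X, Y, Z: int, seed: int, activation: str = "sigmoid",
               ridge: float = 0.0, direct_links: bool = True,
               class_names: list[str] | None = None) -> RNNModel:
    """RVFL: solve on M = [X | H] so direct input-output links carry signal.

    ``direct_links=False`` drops the concatenation and solves on H alone
    (an ELM with a different variant tag), kept for comparison.
    """
    X, Y = _check_xy(X, Y)
    W, b = init_random_layer(X.shape[1], Z, seed)
    H = hidden_output(X, W, b, activation)
    M = np.hstack([X, H]) if direct_links else H
    P = _min_norm_solve(M, Y, ridge)
    return RNNModel("RVFL", W, b, activation, P, None, Z, Y.shape[1], seed,
                    class_names or [])


def train_snn(X, Y, Z: int, seed: int, activation: str = "sigmoid",
              ridge: float = 0.0, class_names: list[str] | None = None) -> RNNModel:
    """SNN: joint solve of weights and output bias on [H | 1]."""
    X, Y = _check_xy(X, Y)
    W, b = init_random_layer(X.shape[1], Z, seed)
    H = hidden_output(X, W, b, activation)
    Hb = np.hstack([H, np.ones((H.shape[0], 1))])
    Pe = _min_norm_solve(Hb, Y, ridge)
    return RNNModel("SNN", W, b, activation, Pe[:-1], Pe[-1], Z, Y.shape[1],
                    seed, class_names or [])


def raw_output(model: RNNModel, X) -> np.ndarray:
    """Continuous network output before the argmax decision."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(
            f"expected {model.input_dim} input features, got {X.shape}")
    H = hidden_output(X, model.W, model.b, model.activation)
    if model.variant == "RVFL" and model.P.shape[0] == model.input_dim + model.Z:
        return np.hstack([X, H]) @ model.P
    O = H @ model.P
    if model.variant == "SNN":
        O = O + model.e
    return O


def predict(model: RNNModel, X) -> np.ndarray:
    """Class labels: argmax of the raw output, ties to the lowest index."""
    return np.argmax(raw_output(model, X), axis=1)


def training_residual(model: RNNModel, X, Y) -> float:
    """Frobenius norm of the fit residual on (X, Y)."""
    return float(np.linalg.norm(raw_output(model, X) - np.asarray(Y, dtype=float)))
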