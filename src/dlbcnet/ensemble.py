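"""Majority-voting ensemble of the three randomized networks (ETRN).

Randomized networks are individually unstable — their accuracy moves with the
random hidden layer — so the deployable classifier votes over an ELM, an
RVFL, and an SNN trained independently on the same features.  The voting
rule: if any two members agree, return the agreed label; if all three
disagree, fall back to the ELM member's prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .rnn import RNNModel, one_hot, predict, raw_output, train_elm, train_rvfl, train_snn


@dataclass
class ETRNModel:
    elm: RNNModel
    rvfl: RNNModel
    snn: RNNModel

    def __post_init__(self):
        ms = (self.elm, self.rvfl, self.snn)
        if len({m.input_dim for m in ms}) != 1 or len({m.class_count for m in ms}) != 1:
            raise ValueError("ensemble members must share input dim and class count")

    @property
    def class_count(self) -> int:
        return self.elm.class_count

    @property
    def members(self) -> tuple[RNNModel, RNNModel, RNNModel]:
        return self.elm, self.rvfl, self.snn

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, m in zip(("elm", "rvfl", "snn"), self.members):
            m.save(directory / name)
        (directory / "manifest.json").write_text(json.dumps(
            {"members": ["elm", "rvfl", "snn"],
             "class_count": self.class_count}, indent=2))

    @classmethod
    def load(cls, directory) -> "ETRNModel":
        directory = Path(directory)
        return cls(*(RNNModel.load(directory / n) for n in ("elm", "rvfl", "snn")))


def majority_vote(r_e: int, r_v: int, r_s: int, m: int | None = None) -> int:
    """Two-of-three agreement wins; three-way disagreement returns the ELM label."""
    if m is not None:
        for r in (r_e, r_v, r_s):
            if not 0 <= r < m:
                raise ValueError(f"label {r} outside [0, {m})")
    if r_e == r_v or r_e == r_s:
        return r_e
    if r_v == r_s:
        return r_v
    return r_e


def majority_vote_array(r_e: np.ndarray, r_v: np.ndarray, r_s: np.ndarray) -> np.ndarray:
    """Vectorized voting rule over aligned member prediction streams."""
    r_e, r_v, r_s = (np.asarray(r) for r in (r_e, r_v, r_s))
    out = r_e.copy()
    vs_agree = (r_v == r_s) & (r_e != r_v) & (r_e != r_s)
    out[vs_agree] = r_v[vs_agree]
    return out


def train_etrn(X, Y, Z: int, seeds: tuple[int, int, int],
               activation: str = "sigmoid", ridge: float = 0.0,
               class_names: list[str] | None = None) -> ETRNModel:
    """Train the three members independently on the same (X, Y)."""
    s1, s2, s3 = seeds
    return ETRNModel(
        elm=train_elm(X, Y, Z, s1, activation, ridge, class_names),
        rvfl=train_rvfl(X, Y, Z, s2, activation, ridge, class_names=class_names),
        snn=train_snn(X, Y, Z, s3, activation, ridge, class_names),
    )


def train_etrn_labels(X, labels, Z: int, seed: int, n_classes: int | None = None,
                      **kwargs) -> ETRNModel:
    """Convenience wrapper: integer labels, member seeds (seed, seed+1, seed+2)."""
    labels = np.asarray(labels, dtype=int)
    m = n_classes if n_classes is not None else int(labels.max()) + 1
    return train_etrn(X, one_hot(labels, m), Z, (seed, seed + 1, seed + 2), **kwargs)


def predict_etrn(model: ETRNModel, X) -> np.ndarray:
    """Element-wise majority vote over the member predictions."""
    return majority_vote_array(*(predict(m, X) for m in model.members))


def decision_scores(model: ETRNModel, X, member: str = "elm") -> np.ndarray:
    """Continuous per-class scores for ROC analysis, from one named member."""
    return raw_output(getattr(model, member), X)
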