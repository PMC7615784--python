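"""Pipeline configuration: defaults, validation, YAML/JSON loading.

Default hyper-parameters follow the reference setting of the method
(mini-batch 10, one fine-tuning epoch, learning rate 1e-4, Z = 400 hidden
nodes, 3000 synthetic images per class); the fixture preset shrinks the
synthetic counts and image sizes to desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .backbone import FinetuneConfig
from .datasets import SplitSpec
from .gan import GANConfig


@dataclass
class PipelineConfig:
    # data source: a class-per-subdirectory image tree, or fixtures if None
    data_root: str | None = None
    fixture_mode: str = "images"       # "images" | "features"
    n_classes: int = 4
    n_per_class: int = 120             # fixture image count per class
    image_size: tuple[int, int] = (32, 32)
    feature_dim: int = 8               # features fixture only
    separation: float = 10.0           # features fixture only
    split: SplitSpec = field(default_factory=SplitSpec)
    # desk-scale GAN preset; pass a full-size GANConfig for real image trees
    gan: GANConfig = field(default_factory=lambda: GANConfig(
        image_size=(32, 32), gen_blocks=4, base_filters=8, noise_dim=32, T=60))
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    Z: int = 400
    n_synthetic_per_class: int = 50    # reference setting: 3000
    seed: int = 0
    out_dir: str = "dlbcnet_out"
    skip_gan: bool = False
    skip_finetune: bool = False
    features_only: bool = False
    trunk_dim: int = 32

    def __post_init__(self):
        if self.Z < 1 or self.n_classes < 2:
            raise ValueError("Z must be >= 1 and n_classes >= 2")
        if self.fixture_mode not in {"images", "features"}:
            raise ValueError("fixture_mode must be 'images' or 'features'")
        if self.data_root is not None and not Path(self.data_root).is_dir():
            raise FileNotFoundError(f"data_root {self.data_root} does not exist")
        if self.features_only and self.data_root is None:
            self.fixture_mode = "features"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for key, sub in (("split", SplitSpec), ("gan", GANConfig),
                         ("finetune", FinetuneConfig)):
            if key in raw and isinstance(raw[key], dict):
                d = raw[key]
                for tup in ("image_size",):
                    if tup in d and isinstance(d[tup], list):
                        d[tup] = tuple(d[tup])
                if "per_class_counts" in d and d["per_class_counts"] is not None:
                    d["per_class_counts"] = {int(k): tuple(v)
                                             for k, v in d["per_class_counts"].items()}
                raw[key] = sub(**d)
        if "image_size" in raw and isinstance(raw["image_size"], list):
            raw["image_size"] = tuple(raw["image_size"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
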