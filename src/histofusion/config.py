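"""Pipeline configuration: a plain dataclass loadable from YAML."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

from .classify import TrainConfig
from .deep import BackboneSpec, DEFAULT_OUTPUT_DIM
from .errors import ConfigurationError
from .fusion import DEFAULT_PCA_COMPONENTS

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # data source: a synthetic preset name ("separable" | "hard") or a
    # manifest CSV path (id,path,label)
    source: str = "separable"
    n_per_class: int = 100
    image_size: tuple[int, int] = (227, 227)
    seed: int = 0

    # preprocessing
    sigma: float = 1.0
    kernel_size: int = 5
    enhance_sign: int = 1

    # split / augmentation
    augment: bool = False

    # features and backbone
    features: str = "deep"                  # deep | handcrafted | fused
    backbone: str = "stub"                  # stub | minicnn | adapter:<id>
    backbone_seed: int = 0
    output_dim: int = DEFAULT_OUTPUT_DIM
    pca_components: int = DEFAULT_PCA_COMPONENTS
    pca_fit_on: str = "train"               # train | all

    # head
    head: str = "svm"                       # svm | ann
    svm_C: float = 1.0
    max_epochs: int = 300
    patience: int = 6
    learning_rate: float = 0.01
    hidden_layout: tuple[int, ...] = (15,)
    loss: str = "cross_entropy"

    # experiment controls
    shuffle_labels: bool = False
    allow_head_feature_override: bool = False
    out_dir: str | None = None

    def __post_init__(self):
        if self.features not in ("deep", "handcrafted", "fused"):
            raise ConfigurationError(f"unknown features mode {self.features!r}")
        if self.head not in ("svm", "ann"):
            raise ConfigurationError(f"unknown head {self.head!r}")
        if self.pca_fit_on not in ("train", "all"):
            raise ConfigurationError("pca_fit_on must be 'train' or 'all'")
        if self.head == "svm" and self.features == "fused" and not self.allow_head_feature_override:
            raise ConfigurationError(
                "the SVM head is paired with deep features; "
                "set allow_head_feature_override to combine it with fused features"
            )
        self.image_size = tuple(self.image_size)
        self.hidden_layout = tuple(self.hidden_layout)

    def backbone_spec(self) -> BackboneSpec:
        return BackboneSpec(name=self.backbone, weights_seed=self.backbone_seed,
                            output_dim=self.output_dim, input_size=self.image_size)

    def train_config(self) -> TrainConfig:
        return TrainConfig(max_epochs=self.max_epochs, patience=self.patience,
                           learning_rate=self.learning_rate, seed=self.seed,
                           hidden_layout=self.hidden_layout, loss=self.loss)

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str) -> PipelineConfig:
    """Load a YAML mapping of PipelineConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a YAML mapping")
    unknown = set(raw) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
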