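"""Single-document YAML run configuration.

A :class:`RunConfig` gathers the augmentation caps, network size,
optimisation settings and loss design under one seed, and round-trips
losslessly through YAML so a run is fully described by one file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .losses import VARIANTS
from .network import UNetConfig
from .synthesis import AugmentationConfig
from .training import TrainConfig


@dataclass
class RunConfig:
    """Everything needed to reproduce a training/evaluation run."""

    seed: int = 0
    loss_variant: str = "sg-nd"
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    network: UNetConfig = field(default_factory=UNetConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.loss_variant.lower() not in VARIANTS:
            raise ValueError(
                f"unknown loss variant {self.loss_variant!r}; choose from {sorted(VARIANTS)}"
            )
        self.loss_variant = self.loss_variant.lower()

    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            return x

        return plain(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        aug = d.get("augmentation", {})
        net = d.get("network", {})
        tr = d.get("training", {})
        return cls(
            seed=int(d.get("seed", 0)),
            loss_variant=d.get("loss_variant", "sg-nd"),
            augmentation=AugmentationConfig(**aug) if not isinstance(aug, AugmentationConfig) else aug,
            network=UNetConfig(**net) if not isinstance(net, UNetConfig) else net,
            training=TrainConfig(**tr) if not isinstance(tr, TrainConfig) else tr,
            paths=dict(d.get("paths", {})),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
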