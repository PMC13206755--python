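"""Configuration objects for the architecture and the training loop.

``ModelConfig.canonical()`` is the published geometry: a ViT-large encoder
(24 blocks, width 1024, 16 heads, 16-pixel patches on a 224-pixel canvas)
with bottleneck adapters, a 2-block mask-transformer decoder, and skip taps
after encoder blocks 6, 12, 18 and 24.  ``ModelConfig.tiny()`` is the same
architecture scaled to a 64-pixel canvas so the full pipeline (including
training) runs in seconds on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class ModelConfig:
    patch_size: int = 16
    canvas_size: int = 224
    embed_dim: int = 1024
    depth: int = 24
    num_heads: int = 16
    adapter_mid: int = 128
    decoder_depth: int = 2
    decoder_dim: int = 1024
    decoder_heads: int = 16
    skip_taps: tuple[int, ...] = (6, 12, 18, 24)
    skip_channels: int = 64
    num_classes: int = 3
    input_size: int = 256
    norm_kind: str = "batch"
    use_pre_adapter: bool = True
    use_post_adapter: bool = True
    use_skips: bool = True
    use_block_adapters: bool = True
    unfreeze_last_n: int = 0

    @property
    def grid_size(self) -> int:
        return self.canvas_size // self.patch_size

    @property
    def num_stages(self) -> int:
        """Number of ×2 upsampling stages: log2(canvas_size / grid_size)."""
        return (self.canvas_size // self.grid_size).bit_length() - 1

    def validate(self) -> "ModelConfig":
        if self.canvas_size % self.patch_size:
            raise ValueError(
                f"canvas_size {self.canvas_size} not divisible by patch_size {self.patch_size}"
            )
        g = self.grid_size
        ratio = self.canvas_size // g
        if g * ratio != self.canvas_size or ratio & (ratio - 1) or ratio < 2:
            raise ValueError(
                f"canvas_size/grid_size = {self.canvas_size}/{g} must be a power of two "
                ">= 2 (number of Post-adapter doubling stages must be a positive integer)"
            )
        if len(self.skip_taps) != 4:
            raise ValueError("skip_taps must list exactly 4 encoder layers")
        if self.use_skips and self.num_stages != 4:
            raise ValueError(
                "skip fusion requires 4 upsampling stages "
                f"(canvas/grid = 2^4), got {self.num_stages}"
            )
        if any(b <= a for a, b in zip(self.skip_taps, self.skip_taps[1:])):
            raise ValueError(f"skip_taps must be strictly increasing, got {self.skip_taps}")
        if max(self.skip_taps) > self.depth:
            raise ValueError(
                f"skip tap {max(self.skip_taps)} exceeds encoder depth {self.depth}"
            )
        if self.num_classes not in (2, 3):
            raise ValueError("num_classes must be 2 (disc only) or 3 (joint disc+cup)")
        if self.embed_dim % self.num_heads or self.decoder_dim % self.decoder_heads:
            raise ValueError("embedding width must be divisible by the head count")
        if self.norm_kind not in ("batch", "group"):
            raise ValueError(f"norm_kind must be 'batch' or 'group', got {self.norm_kind!r}")
        if not 0 <= self.unfreeze_last_n <= self.depth:
            raise ValueError("unfreeze_last_n out of range")
        return self

    @classmethod
    def canonical(cls, num_classes: int = 3, **overrides) -> "ModelConfig":
        return cls(num_classes=num_classes, **overrides).validate()

    @classmethod
    def tiny(cls, num_classes: int = 3, **overrides) -> "ModelConfig":
        """CPU-scale test geometry: same structure, 64-pixel canvas (grid 4)."""
        base = dict(
            patch_size=16, canvas_size=64, embed_dim=64, depth=4, num_heads=4,
            adapter_mid=16, decoder_depth=2, decoder_dim=64, decoder_heads=4,
            skip_taps=(1, 2, 3, 4), skip_channels=16, num_classes=num_classes,
            input_size=64, norm_kind="group",
        )
        base.update(overrides)
        return cls(**base).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["skip_taps"] = list(self.skip_taps)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "skip_taps" in d:
            d["skip_taps"] = tuple(d["skip_taps"])
        return cls(**d).validate()


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    weight_decay: float = 0.001
    batch_size: int = 32
    max_epochs: int = 500           # published runs used up to 20,000
    seed: int = 112316
    augmentation_strategy: str = "none"
    validation_interval: int = 1
    early_stop_dsc: float | None = None

    def validate(self) -> "TrainConfig":
        if min(self.learning_rate, self.weight_decay) < 0:
            raise ValueError("learning_rate and weight_decay must be nonnegative")
        if min(self.batch_size, self.max_epochs, self.validation_interval) < 1:
            raise ValueError("batch_size, max_epochs, validation_interval must be >= 1")
        if self.augmentation_strategy not in ("none", "spatial", "designed"):
            raise ValueError(
                f"augmentation_strategy must be none|spatial|designed, "
                f"got {self.augmentation_strategy!r}"
            )
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TrainConfig keys: {sorted(unknown)}")
        return cls(**d).validate()


@dataclass
class RunConfig:
    """Merged model + training + data settings, round-trippable through YAML."""

    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    crop_size: int = 800
    seed: int = 112316
    config_path: str | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "train": self.train.to_dict(),
            "crop_size": self.crop_size,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict, config_path: str | None = None) -> "RunConfig":
        known = {"model", "train", "crop_size", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(
            model=ModelConfig.from_dict(d.get("model", {})),
            train=TrainConfig.from_dict(d.get("train", {})),
            crop_size=int(d.get("crop_size", 800)),
            seed=int(d.get("seed", 112316)),
            config_path=config_path,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {}, config_path=str(path))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)
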