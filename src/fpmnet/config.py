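"""Configuration objects for the network, training runs, and the synthetic
fundus generator, with YAML (de)serialization.

``NetworkConfig`` fully determines the computation graph: the same config
always builds the same layer census and parameter shapes, so the frozen
``fpmnet-default`` profile pins the architecture the headline parameter
budgets refer to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a config violates a structural invariant."""


@dataclass
class NetworkConfig:
    """Architectural hyper-parameters of FPM-Net.

    The dense feature down-sampling blocks (FDB) are named DFB-A, DFB-B, ...
    in block-index order.  ``fdb_channel_schedule[i]`` is the output channel
    count of block ``i``; each of its ``convs_per_block`` convolutions emits
    ``schedule[i] / convs_per_block`` channels (dense growth).  Blocks at
    index >= ``depthwise_separable_from_block`` use depth-wise separable
    convolutions.  ``pooling_ops`` 2x down-samplings sit between the first
    blocks, and the shallow up-sampling path (FUB) undoes them with
    ``pooling_ops`` stride-2 transposed-convolution stages of widths
    ``fub_channel_schedule``.
    """

    input_height: int = 256
    input_width: int = 256
    input_channels: int = 3
    num_classes: int = 2
    fdb_blocks: int = 4
    fdb_channel_schedule: list[int] = field(default_factory=lambda: [64, 128, 256, 384])
    convs_per_block: int = 2
    kernel_size: int = 3
    dilation_rate: int = 2
    use_fpb: bool = True
    fpb_channels: int = 16
    depthwise_separable_from_block: int = 2
    pooling_ops: int = 3
    bottleneck_channels: int = 2
    fub_channel_schedule: list[int] = field(default_factory=lambda: [320, 160, 64])
    fif_channels: int = 32

    def validate(self) -> None:
        div = 2 ** self.pooling_ops
        if self.input_height % div:
            raise ConfigurationError(
                f"input_height={self.input_height} not divisible by 2^pooling_ops={div}")
        if self.input_width % div:
            raise ConfigurationError(
                f"input_width={self.input_width} not divisible by 2^pooling_ops={div}")
        if self.num_classes != 2:
            raise ConfigurationError("num_classes must be 2 (vessel, background)")
        if len(self.fdb_channel_schedule) != self.fdb_blocks:
            raise ConfigurationError(
                f"fdb_channel_schedule length {len(self.fdb_channel_schedule)} "
                f"!= fdb_blocks {self.fdb_blocks}")
        for ch in self.fdb_channel_schedule:
            if ch % self.convs_per_block:
                raise ConfigurationError(
                    f"channel count {ch} not divisible by convs_per_block")
        if self.pooling_ops > max(self.fdb_blocks - 1, 0):
            raise ConfigurationError(
                "pooling_ops must be at most fdb_blocks - 1 "
                "(poolings sit between down-sampling blocks)")
        if len(self.fub_channel_schedule) != self.pooling_ops:
            raise ConfigurationError(
                f"fub_channel_schedule length {len(self.fub_channel_schedule)} "
                f"!= pooling_ops {self.pooling_ops}")
        if self.fpb_channels < 1 or self.fif_channels < 1:
            raise ConfigurationError("channel counts must be positive")

    def with_updates(self, **kwargs) -> "NetworkConfig":
        d = asdict(self)
        d.update(kwargs)
        return NetworkConfig(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        cfg.validate()
        return cfg


def default_config() -> NetworkConfig:
    """The frozen ``fpmnet-default`` architecture (as shipped in YAML)."""
    with resources.as_file(
            resources.files("fpmnet.configs") / "fpmnet-default.yaml") as p:
        return NetworkConfig.from_yaml(p)


def small_config(size: int = 64) -> NetworkConfig:
    """A reduced-width profile for desk-scale experiments and tests."""
    return NetworkConfig(
        input_height=size, input_width=size,
        fdb_channel_schedule=[8, 16, 24, 32],
        fub_channel_schedule=[24, 16, 8],
        fpb_channels=8, fif_channels=8,
    )


@dataclass
class TrainConfig:
    """Optimization hyper-parameters (defaults follow the published recipe)."""

    learning_rate: float = 0.00005
    optimizer_epsilon: float = 0.000001
    l2_coefficient: float = 0.0001
    batch_size: int = 16
    epochs: int = 25
    max_iterations: int = 5000
    seed: int = 0
    device: str = "cpu"

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")


@dataclass
class SyntheticParams:
    """Seedable controls of the synthetic fundus generator.

    Vessels are drawn darker than the background by ``vessel_contrast``, as
    in real fundus photographs; ``fov_margin`` insets the circular field of
    view from the image border.
    """

    height: int = 256
    width: int = 256
    seed: int = 0
    n_roots: int = 7
    branch_prob: float = 0.07
    width_root: float = 5.0
    width_decay: float = 0.82
    tortuosity: float = 0.16
    vessel_contrast: float = 0.35
    background_noise_sd: float = 0.03
    fov_margin: int = 6

    def validate(self) -> None:
        if not (0 < self.width_decay < 1):
            raise ConfigurationError("width_decay must lie in (0, 1)")
        if not (0 <= self.branch_prob <= 1):
            raise ConfigurationError("branch_prob must lie in [0, 1]")
        if self.width_root < 1:
            raise ConfigurationError("width_root must be >= 1 pixel")
        if min(self.height, self.width) <= 2 * self.fov_margin:
            raise ConfigurationError("field of view has zero area")
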