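"""Model configuration and builder for the quadratic / linear 1-D CNNs.

Default architecture (canonical input length 2048, reached by linear
resampling of the 701-band spectrum):

    L1: conv k=64 s=8, 1->16 ch (quadratic or linear stem) + BN + ReLU + maxpool 2
    L2: conv k=3  s=1, 16->16  + BN + ReLU + maxpool 2
    L3: conv k=3  s=1, 16->8   + BN + ReLU
    head: flatten (512) -> dense 100 -> ReLU -> dropout -> dense n_classes

2048 -> 256 -> 128 -> 128 -> 64, times 8 channels = the declared 512-dim
flatten.  The builder traces the conv arithmetic and rejects configurations
whose traced flatten size disagrees with the declared one.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from watercore.nn.layers import (
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    MaxPool1d,
    Network,
    QuadConv1d,
    ReLU,
    same_padding,
)


class ConfigError(ValueError):
    """Inconsistent model configuration."""


@dataclass
class ConvSpec:
    kernel: int
    stride: int
    out_channels: int
    pool: int = 0  # 0 = no pooling after this layer

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.stride < 1 or self.out_channels < 1:
            raise ConfigError("kernel, stride and channels must be >= 1")
        if self.pool < 0:
            raise ConfigError("pool size must be >= 0")


@dataclass
class ModelConfig:
    """Architecture + training hyperparameters.

    ``lr=1e-3`` is the toolkit default; ``paper_profile()`` selects the
    published settings (lr 0.5, 500 epochs) instead.
    """

    input_length: int = 2048
    n_classes: int = 4
    conv_layers: list[ConvSpec] = field(
        default_factory=lambda: [
            ConvSpec(kernel=64, stride=8, out_channels=16, pool=2),
            ConvSpec(kernel=3, stride=1, out_channels=16, pool=2),
            ConvSpec(kernel=3, stride=1, out_channels=8, pool=0),
        ]
    )
    flatten_size: int = 512
    hidden_size: int = 100
    dropout: float = 0.5
    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        self.conv_layers = [
            c if isinstance(c, ConvSpec) else ConvSpec(**c) for c in self.conv_layers
        ]
        if self.input_length < self.conv_layers[0].kernel:
            raise ConfigError(
                f"input_length {self.input_length} < first kernel "
                f"{self.conv_layers[0].kernel}"
            )

    @classmethod
    def paper_profile(cls, **overrides) -> "ModelConfig":
        """Published training settings: RAdam, lr 0.5, wd 1e-4, batch 32, 500 epochs."""
        defaults = dict(lr=0.5, weight_decay=1e-4, batch_size=32, epochs=500)
        defaults.update(overrides)
        return cls(**defaults)

    def traced_flatten_size(self) -> int:
        length = self.input_length
        channels = 1
        for spec in self.conv_layers:
            _, _, length = same_padding(length, spec.kernel, spec.stride)
            channels = spec.out_channels
            if spec.pool:
                if length % spec.pool:
                    raise ConfigError(
                        f"length {length} not divisible by pool {spec.pool}"
                    )
                length //= spec.pool
        return channels * length

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_layers"] = [ConvSpec(**c) for c in d.get("conv_layers", [])]
        if not d["conv_layers"]:
            d.pop("conv_layers")
        return cls(**d)


def build_model(cfg: ModelConfig, quadratic: bool = True) -> Network:
    """Build the network; ``quadratic=False`` gives the linear-stem baseline."""
    traced = cfg.traced_flatten_size()
    if traced != cfg.flatten_size:
        raise ConfigError(
            f"declared flatten size {cfg.flatten_size} != traced size {traced}"
        )
    rng = np.random.default_rng(cfg.seed)
    layers: list = []
    in_ch = 1
    for i, spec in enumerate(cfg.conv_layers):
        conv_cls = QuadConv1d if (quadratic and i == 0) else Conv1d
        layers.append(conv_cls(in_ch, spec.out_channels, spec.kernel, spec.stride, rng))
        layers.append(BatchNorm1d(spec.out_channels))
        layers.append(ReLU())
        if spec.pool:
            layers.append(MaxPool1d(spec.pool))
        in_ch = spec.out_channels
    layers.append(Flatten())
    layers.append(Dense(cfg.flatten_size, cfg.hidden_size, rng))
    layers.append(ReLU())
    layers.append(Dropout(cfg.dropout, rng))
    layers.append(Dense(cfg.hidden_size, cfg.n_classes, rng))
    return Network(layers)


def trace_shapes(net: Network, input_length: int) -> list[tuple[str, tuple]]:
    """Run a dummy forward pass, reporting every intermediate tensor shape."""
    x = np.zeros((1, 1, input_length))
    trace = [("input", x.shape)]
    for layer in net.layers:
        x = layer.forward(x, training=False)
        trace.append((layer.name, x.shape))
    return trace
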