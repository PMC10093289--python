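"""Generator and discriminator architectures.

The generator is a fully convolutional encoder-decoder: a 3x3 stem
convolution, three (dense block -> 1x1 transition -> 2x2 max-pool) encoder
stages, three (2x2 transposed convolution -> skip concatenation -> dense
block) decoder stages, and a final 1x1 convolution with a sigmoid that emits
a per-pixel foreground probability map the same size as the input.

A dense block of L layers, each BN -> ReLU -> 3x3 conv producing ``growth``
channels, concatenates every layer's output with all previous features, so
its output carries ``in_channels + L * growth`` channels.

The discriminator is a six-layer multi-scale feature extractor over the
channel-concatenation of an image and a candidate mask. Each layer is
conv -> BN -> leaky ReLU; the per-layer activations form the feature pyramid
consumed by the L1 adversarial loss, and a global-average-pool + linear head
provides a scalar real/fake score.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .nn import (BatchNorm2d, Conv2d, ConvTranspose2d, Linear, MaxPool2d,
                 Module, Tensor)


class ShapeError(ValueError):
    """Raised when an input violates a network's spatial-shape contract."""


_ALLOWED_KERNELS = {7, 5, 4, 3}


@dataclasses.dataclass(frozen=True)
class DenseBlockSpec:
    """Shape of one densely connected block."""

    n_layers: int = 4
    growth: int = 4

    def __post_init__(self):
        if self.n_layers < 0 or self.growth <= 0:
            raise ValueError("dense block needs n_layers >= 0 and growth > 0")

    def out_channels(self, in_channels: int) -> int:
        return in_channels + self.n_layers * self.growth


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    in_channels: int = 1
    base_channels: int = 8
    dense: DenseBlockSpec = DenseBlockSpec()
    n_scales: int = 3
    head_bias_init: float = -2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_scales != 3:
            raise ValueError("the generator uses exactly 3 pooling stages")
        if self.in_channels < 1 or self.base_channels < 1:
            raise ValueError("channel counts must be positive")

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["kind"] = "generator"
        return d

    @classmethod
    def from_json(cls, d: dict) -> "GeneratorConfig":
        d = {k: v for k, v in d.items() if k != "kind"}
        if isinstance(d.get("dense"), dict):
            d["dense"] = DenseBlockSpec(**d["dense"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class DiscriminatorConfig:
    in_channels: int = 2  # image + mask stacked on the channel axis
    kernel_sizes: tuple[int, ...] = (7, 5, 4, 4, 3, 3)
    strides: tuple[int, ...] = (2, 2, 2, 2, 1, 1)
    channel_schedule: tuple[int, ...] = (8, 16, 32, 32, 32, 32)
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        n = len(self.kernel_sizes)
        if n != 6:
            raise ValueError("the discriminator has exactly 6 layers")
        if len(self.strides) != n or len(self.channel_schedule) != n:
            raise ValueError("kernel_sizes, strides and channel_schedule "
                             "must all have 6 entries")
        bad = set(self.kernel_sizes) - _ALLOWED_KERNELS
        if bad:
            raise ValueError(
                f"kernel sizes must come from {sorted(_ALLOWED_KERNELS)}, "
                f"got {sorted(bad)}")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")

    @property
    def n_layers(self) -> int:
        return 6

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["kind"] = "discriminator"
        return d

    @classmethod
    def from_json(cls, d: dict) -> "DiscriminatorConfig":
        d = {k: v for k, v in d.items() if k != "kind"}
        for key in ("kernel_sizes", "strides", "channel_schedule"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class DenseBlock(Module):
    """L x (BN -> ReLU -> 3x3 conv) with dense channel concatenation."""

    def __init__(self, in_channels: int, spec: DenseBlockSpec, *,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.spec = spec
        self.norms: list[BatchNorm2d] = []
        self.convs: list[Conv2d] = []
        ch = in_channels
        for _ in range(spec.n_layers):
            self.norms.append(BatchNorm2d(ch))
            self.convs.append(Conv2d(ch, spec.growth, 3, padding=1, rng=rng))
            ch += spec.growth
        self.out_channels = ch

    def forward(self, x: Tensor) -> Tensor:
        # channels-last: concatenation on the trailing axis
        features = x
        for bn, conv in zip(self.norms, self.convs):
            new = conv(nn.relu(bn(features)))
            features = nn.concat([features, new], axis=-1)
        return features


class Generator(Module):
    def __init__(self, config: GeneratorConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(int(config.seed))
        spec = config.dense
        self.stem = Conv2d(config.in_channels, config.base_channels, 3,
                           padding=1, rng=rng)
        self.pool = MaxPool2d(2)
        self.enc_blocks: list[DenseBlock] = []
        self.enc_trans: list[Conv2d] = []
        skip_channels = []
        ch = config.base_channels
        for _ in range(3):
            block = DenseBlock(ch, spec, rng=rng)
            trans_ch = max(block.out_channels // 2, 1)
            self.enc_blocks.append(block)
            self.enc_trans.append(
                Conv2d(block.out_channels, trans_ch, 1, rng=rng))
            skip_channels.append(trans_ch)
            ch = trans_ch
        self.dec_up: list[ConvTranspose2d] = []
        self.dec_blocks: list[DenseBlock] = []
        for skip_ch in reversed(skip_channels):
            self.dec_up.append(ConvTranspose2d(ch, skip_ch, rng=rng))
            block = DenseBlock(2 * skip_ch, spec, rng=rng)
            self.dec_blocks.append(block)
            ch = block.out_channels
        self.head = Conv2d(ch, 1, 1, rng=rng)
        # bias the initial probability map toward background: foreground is
        # a small fraction of each slice, and starting near the class prior
        # keeps early Dice gradients informative
        self.head.bias.data[:] = config.head_bias_init

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if isinstance(x, np.ndarray):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4:
            raise ShapeError(
                f"generator expects (N, C, H, W) input, got shape {x.shape}")
        _, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ShapeError(
                f"generator built for {self.config.in_channels} channel(s), "
                f"got {c}")
        if h % 8 or w % 8:
            raise ShapeError(
                f"input height and width must be divisible by 8 (three 2x2 "
                f"pooling stages), got {h}x{w}")
        h_ = self.stem(nn.transpose(x, (0, 2, 3, 1)))  # to channels-last
        skips = []
        for block, trans in zip(self.enc_blocks, self.enc_trans):
            h_ = trans(block(h_))
            skips.append(h_)
            h_ = self.pool(h_)
        for up, block, skip in zip(self.dec_up, self.dec_blocks,
                                   reversed(skips)):
            h_ = up(h_)
            h_ = block(nn.concat([h_, skip], axis=-1))
        out = nn.sigmoid(self.head(h_))
        return nn.transpose(out, (0, 3, 1, 2))  # back to channels-first


class Discriminator(Module):
    def __init__(self, config: DiscriminatorConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(int(config.seed))
        self.convs: list[Conv2d] = []
        self.norms: list[BatchNorm2d] = []
        ch = config.in_channels
        for k, s, out_ch in zip(config.kernel_sizes, config.strides,
                                config.channel_schedule):
            # padding keeps ceil(H/s) spatial size for odd k, H/s for k=4,s=2
            pad = (k - 1) // 2 if k % 2 else (k - s) // 2
            self.convs.append(Conv2d(ch, out_ch, k, stride=s, padding=pad,
                                     rng=rng))
            self.norms.append(BatchNorm2d(out_ch))
            ch = out_ch
        self.decision = Linear(ch, 1, rng=rng)

    def forward(self, image: Tensor | np.ndarray, mask: Tensor | np.ndarray
                ) -> tuple[list[Tensor], Tensor]:
        """Judge ``mask`` in the context of ``image``.

        Returns the six-level feature pyramid and one raw decision score per
        batch item (pass through a sigmoid for a probability).
        """
        if isinstance(image, np.ndarray):
            image = Tensor(np.asarray(image, dtype=np.float32))
        if isinstance(mask, np.ndarray):
            mask = Tensor(np.asarray(mask, dtype=np.float32))
        if image.shape[-2:] != mask.shape[-2:]:
            raise ShapeError(
                f"image {image.shape[-2:]} and mask {mask.shape[-2:]} "
                f"spatial sizes differ")
        h = nn.concat([nn.transpose(image, (0, 2, 3, 1)),
                       nn.transpose(mask, (0, 2, 3, 1))], axis=-1)
        pyramid: list[Tensor] = []
        slope = self.config.leaky_slope
        for conv, bn in zip(self.convs, self.norms):
            h = nn.leaky_relu(bn(conv(h)), slope)
            pyramid.append(h)
        pooled = h.mean(axis=(1, 2))
        score = self.decision(pooled)
        return pyramid, score


def build_generator(config: GeneratorConfig | None = None) -> Generator:
    return Generator(config or GeneratorConfig())


def build_discriminator(config: DiscriminatorConfig | None = None
                        ) -> Discriminator:
    return Discriminator(config or DiscriminatorConfig())


def count_parameters(network: Module) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in network.parameters()))


def save_config(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_json(), fh, indent=2)


def load_config(path: str | Path):
    with open(path) as fh:
        d = json.load(fh)
    kind = d.get("kind")
    if kind == "generator":
        return GeneratorConfig.from_json(d)
    if kind == "discriminator":
        return DiscriminatorConfig.from_json(d)
    raise ValueError(f"unknown config kind: {kind!r}")
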