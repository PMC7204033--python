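"""The fully-convolutional densely connected 2D encoder–decoder.

The network follows the DenseNet segmentation pattern: a stem convolution,
`levels` encoder stages (dense block, then transition-down), a bottleneck
dense block, and `levels` decoder stages (transition-up, concatenation with
the stored encoder skip, dense block), closed by a 1×1 convolution and a
softmax over the two classes (cavity foreground vs background).

Structural conventions, chosen so the default configuration reproduces the
published channel/resolution table exactly:

* each dense unit is batch-norm → ReLU → 3×3 convolution → dropout, and a
  dense block of U units concatenates its way from C to C + U·g channels
  (growth rate g);
* the transition-down dense unit is channel-preserving (C → C convolution,
  no concatenation) and is followed by 2×2 max pooling with floor
  semantics;
* the transition-up is bilinear interpolation to the stored skip's spatial
  size followed by a 3×3 convolution compressing to U·g channels;
* the stem is convolution + dropout only (no normalization).

With the defaults (stem 48, g = 12, U = 4, 4 levels) the encoder trace is
48 → 96 → 144 → 192 → 240 → 288 and the decoder trace 336 → 288 → 240 →
192, ending in a 2-channel 1×1 convolution.  Because upsampling targets the
stored skip sizes, any input with sides ≥ 2^levels works — no divisibility
requirement.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .layers import (
    BatchNorm2d,
    BilinearResize,
    Conv2d,
    Dropout,
    MaxPool2,
    Module,
    ReLU,
    softmax,
)

__all__ = [
    "ArchitectureConfig",
    "SizeError",
    "channel_trace",
    "build_network",
    "FCDenseNet",
    "save_checkpoint",
    "load_checkpoint",
]


class SizeError(ValueError):
    """Input spatial extent below the architecture minimum."""


@dataclass(frozen=True)
class ArchitectureConfig:
    """Structural hyperparameters of the segmentation network."""

    in_channels: int = 4
    stem_channels: int = 48
    growth_rate: int = 12
    units_per_block: int = 4
    levels: int = 4
    dropout_p: float = 0.2
    kernel: int = 3
    classes: int = 2

    def __post_init__(self) -> None:
        counts = {
            "in_channels": self.in_channels,
            "stem_channels": self.stem_channels,
            "growth_rate": self.growth_rate,
            "units_per_block": self.units_per_block,
            "levels": self.levels,
            "kernel": self.kernel,
            "classes": self.classes,
        }
        bad = [k for k, v in counts.items() if int(v) != v or v < 1]
        if bad:
            raise ValueError(f"counts must be integers >= 1, offending: {bad}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError(f"dropout_p must be in [0, 1), got {self.dropout_p}")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd for 'same' padding")

    @property
    def block_growth(self) -> int:
        """Channels added by one dense block (= compression target of a
        transition-up)."""
        return self.units_per_block * self.growth_rate

    @property
    def min_extent(self) -> int:
        return 2 ** self.levels

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        return cls(**d)


def channel_trace(
    config: ArchitectureConfig, input_size: tuple[int, int]
) -> list[tuple[str, int, tuple[int, int]]]:
    """Per-building-block (name, output channels, spatial extent) trace.

    The extent listed for each row is the one at which that block computes;
    pooling halves with floor semantics, and upsampling restores the exact
    stored skip extents.
    """
    h, w = input_size
    if min(h, w) < config.min_extent:
        raise SizeError(
            f"input {input_size} too small: each side must be >= {config.min_extent} "
            f"(2^levels) for {config.levels} levels"
        )
    g = config.block_growth
    rows: list[tuple[str, int, tuple[int, int]]] = []
    rows.append(("input", config.in_channels, (h, w)))
    rows.append(("convolution+dropout", config.stem_channels, (h, w)))
    c = config.stem_channels
    skip_channels: list[int] = []
    skip_sizes: list[tuple[int, int]] = []
    for _ in range(config.levels):
        c += g
        rows.append(("dense block+transition down", c, (h, w)))
        skip_channels.append(c)
        skip_sizes.append((h, w))
        h, w = h // 2, w // 2
    c += g
    rows.append(("dense block", c, (h, w)))
    for sc, (sh, sw) in zip(reversed(skip_channels), reversed(skip_sizes)):
        c = g + sc + g  # transition-up output + skip + dense-block growth
        rows.append(("transition up+dense block", c, (sh, sw)))
        h, w = sh, sw
    rows.append(("1x1 convolution", config.classes, (h, w)))
    rows.append(("softmax", config.classes, (h, w)))
    return rows


class DenseUnit(Module):
    """batch-norm → ReLU → convolution → dropout."""

    def __init__(self, cin: int, cout: int, config: ArchitectureConfig,
                 rng: np.random.Generator, dtype):
        self.bn = BatchNorm2d(cin, dtype=dtype)
        self.relu = ReLU()
        self.conv = Conv2d(cin, cout, config.kernel, rng, dtype=dtype)
        self.drop = Dropout(config.dropout_p)

    def _children(self):
        return {"bn": self.bn, "conv": self.conv}

    def forward(self, x, training=False, rng=None):
        y = self.bn.forward(x, training)
        y = self.relu.forward(y)
        y = self.conv.forward(y)
        return self.drop.forward(y, training, rng)

    def backward(self, dy):
        d = self.drop.backward(dy)
        d = self.conv.backward(d)
        d = self.relu.backward(d)
        return self.bn.backward(d)


class DenseBlock(Module):
    """U densely connected units; output has cin + U·growth channels."""

    def __init__(self, cin: int, config: ArchitectureConfig,
                 rng: np.random.Generator, dtype):
        self.cin = cin
        self.units = [
            DenseUnit(cin + i * config.growth_rate, config.growth_rate, config, rng, dtype)
            for i in range(config.units_per_block)
        ]
        self.cout = cin + config.units_per_block * config.growth_rate

    def _children(self):
        return {f"unit{i}": u for i, u in enumerate(self.units)}

    def forward(self, x, training=False, rng=None):
        cur = x
        self._cins = []
        for unit in self.units:
            self._cins.append(cur.shape[-1])
            u = unit.forward(cur, training, rng)
            cur = np.concatenate([cur, u], axis=-1)
        return cur

    def backward(self, dy):
        d = dy
        for unit, cin in zip(reversed(self.units), reversed(self._cins)):
            d_prev, d_u = d[..., :cin], d[..., cin:]
            d = d_prev + unit.backward(d_u)
        self._cins = None
        return d


class TransitionDown(Module):
    """Channel-preserving dense unit followed by 2×2 max pooling."""

    def __init__(self, channels: int, config: ArchitectureConfig,
                 rng: np.random.Generator, dtype):
        self.unit = DenseUnit(channels, channels, config, rng, dtype)
        self.pool = MaxPool2()

    def _children(self):
        return {"unit": self.unit}

    def forward(self, x, training=False, rng=None):
        return self.pool.forward(self.unit.forward(x, training, rng))

    def backward(self, dy):
        return self.unit.backward(self.pool.backward(dy))


class TransitionUp(Module):
    """Bilinear upsampling to the skip's extent, then a compressing conv."""

    def __init__(self, cin: int, cout: int, config: ArchitectureConfig,
                 rng: np.random.Generator, dtype):
        self.resize = BilinearResize()
        self.conv = Conv2d(cin, cout, config.kernel, rng, dtype=dtype)

    def _children(self):
        return {"conv": self.conv}

    def forward(self, x, target: tuple[int, int], training=False, rng=None):
        return self.conv.forward(self.resize.forward(x, target))

    def backward(self, dy):
        return self.resize.backward(self.conv.backward(dy))


class FCDenseNet(Module):
    """The full encoder–decoder; see the module docstring for the layout."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        g = config.block_growth

        self.stem_conv = Conv2d(config.in_channels, config.stem_channels,
                                config.kernel, rng, dtype=dtype)
        self.stem_drop = Dropout(config.dropout_p)

        c = config.stem_channels
        self.down_blocks: list[DenseBlock] = []
        self.tds: list[TransitionDown] = []
        self._skip_channels: list[int] = []
        for _ in range(config.levels):
            block = DenseBlock(c, config, rng, dtype)
            c = block.cout
            self.down_blocks.append(block)
            self._skip_channels.append(c)
            self.tds.append(TransitionDown(c, config, rng, dtype))
        self.bottleneck = DenseBlock(c, config, rng, dtype)
        c = self.bottleneck.cout

        self.tus: list[TransitionUp] = []
        self.up_blocks: list[DenseBlock] = []
        for sc in reversed(self._skip_channels):
            self.tus.append(TransitionUp(c, g, config, rng, dtype))
            block = DenseBlock(g + sc, config, rng, dtype)
            self.up_blocks.append(block)
            c = block.cout
        self.final = Conv2d(c, config.classes, 1, rng, dtype=dtype)

    def _children(self):
        children: dict[str, Module] = {"stem_conv": self.stem_conv}
        for i, b in enumerate(self.down_blocks):
            children[f"down{i}"] = b
        for i, t in enumerate(self.tds):
            children[f"td{i}"] = t
        children["bottleneck"] = self.bottleneck
        for i, t in enumerate(self.tus):
            children[f"tu{i}"] = t
        for i, b in enumerate(self.up_blocks):
            children[f"up{i}"] = b
        children["final"] = self.final
        return children

    def forward_logits(self, x: np.ndarray, training: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        """Class logits, NCHW in and out; internals run channels-last."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, H, W) input, got {x.shape}"
            )
        if min(x.shape[2], x.shape[3]) < self.config.min_extent:
            raise SizeError(
                f"spatial extent {x.shape[2:]} below minimum {self.config.min_extent}"
            )
        y = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
        y = self.stem_drop.forward(self.stem_conv.forward(y), training, rng)
        skips: list[np.ndarray] = []
        for block, td in zip(self.down_blocks, self.tds):
            y = block.forward(y, training, rng)
            skips.append(y)
            y = td.forward(y, training, rng)
        y = self.bottleneck.forward(y, training, rng)
        for tu, block, skip in zip(self.tus, self.up_blocks, reversed(skips)):
            y = tu.forward(y, skip.shape[1:3], training, rng)
            y = np.concatenate([skip, y], axis=-1)
            y = block.forward(y, training, rng)
        logits = self.final.forward(y)
        return np.ascontiguousarray(logits.transpose(0, 3, 1, 2))

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-pixel class probabilities, shape (N, classes, H, W)."""
        return softmax(self.forward_logits(x, training, rng), axis=1)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the logits (NCHW) through the net."""
        d = np.ascontiguousarray(
            np.asarray(dlogits, dtype=self.dtype).transpose(0, 2, 3, 1)
        )
        d = self.final.backward(d)
        skip_grads: list[np.ndarray | None] = [None] * self.config.levels
        # decoder stage i consumed skip (levels-1-i), so in reversed order the
        # i-th stage here returns the gradient for skip i
        for i, (tu, block) in enumerate(zip(reversed(self.tus), reversed(self.up_blocks))):
            d = block.backward(d)
            sc = self._skip_channels[i]
            skip_grads[i] = d[..., :sc]
            d = tu.backward(d[..., sc:])
        d = self.bottleneck.backward(d)
        for level in range(self.config.levels - 1, -1, -1):
            d = self.tds[level].backward(d)
            d = d + skip_grads[level]
            d = self.down_blocks[level].backward(d)
        d = self.stem_drop.backward(d)
        self.stem_conv.backward(d)


def build_network(config: ArchitectureConfig, seed: int = 0,
                  dtype=np.float32) -> FCDenseNet:
    """Build the network with rectifier-scaled random initialization."""
    return FCDenseNet(config, seed=seed, dtype=dtype)


def save_checkpoint(net: FCDenseNet, path: str | Path) -> None:
    """Save parameters, normalization statistics and the config to ``path``."""
    arrays = {f"param/{name}": p.data for name, p in net.named_params()}
    arrays.update({f"buffer/{name}": b for name, b in net.named_buffers()})
    arrays["config"] = np.frombuffer(
        json.dumps(net.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(str(path), **arrays)


def load_checkpoint(path: str | Path, dtype=np.float32) -> FCDenseNet:
    with np.load(str(path)) as data:
        config = ArchitectureConfig.from_dict(
            json.loads(bytes(data["config"].tobytes()).decode())
        )
        net = FCDenseNet(config, seed=0, dtype=dtype)
        params = dict(net.named_params())
        for key in data.files:
            if key.startswith("param/"):
                name = key[len("param/"):]
                np.copyto(params[name].data, data[key])
            elif key.startswith("buffer/"):
                net.set_buffer(key[len("buffer/"):], data[key])
    return net
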