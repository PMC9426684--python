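"""Encoder-decoder segmentation network (UNet) in NumPy.

Topology: ``depth`` encoder levels of two conv-BN-ReLU blocks with 2x2 max
pooling between levels, a two-block bottleneck, and a mirrored decoder of
nearest-neighbour upsampling + channel-halving convolution, skip
concatenation and two conv-BN-ReLU blocks.  Dropout (default 30%) acts in
the first three up-sampling convolutional blocks.  A 1x1 convolution and a
channel softmax produce the 4-channel segmentation posterior (background,
myocardium, LV cavity, scar).

The default configuration is deliberately scaled down (8 base filters,
64 px frames) so the model trains on a CPU in seconds; the full-scale
topology is the same graph with more filters and 224 px inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2D,
    Dropout,
    MaxPool2,
    ReLU,
    SoftmaxChannels,
    UpsampleNearest2,
)


@dataclass(frozen=True)
class UNetConfig:
    input_channels: int = 32
    output_channels: int = 4
    base_filters: int = 8
    depth: int = 3
    dropout_rate: float = 0.3
    n_dropout_blocks: int = 3  # dropout in the first three up-sampling blocks
    image_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.image_size % (2**self.depth) != 0:
            raise ValueError("image_size must be divisible by the down-sampling factor")


class _ConvBlock:
    """conv -> batch-norm -> ReLU."""

    def __init__(self, cin, cout, name, rng):
        self.conv = Conv2D(cin, cout, 3, name=f"{name}.conv", rng=rng)
        self.bn = BatchNorm2d(cout, name=f"{name}.bn")
        self.act = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train):
        return self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, grad):
        return self.conv.backward(self.bn.backward(self.act.backward(grad)))


class UNet:
    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        self.enc = []
        cin = cfg.input_channels
        for d in range(cfg.depth):
            cout = f * 2**d
            self.enc.append(
                (_ConvBlock(cin, cout, f"enc{d}a", rng), _ConvBlock(cout, cout, f"enc{d}b", rng))
            )
            cin = cout
        self.pools = [MaxPool2() for _ in range(cfg.depth)]
        cb = f * 2**cfg.depth
        self.bottleneck = (
            _ConvBlock(cin, cb, "bota", rng),
            _ConvBlock(cb, cb, "botb", rng),
        )
        self.ups, self.upconvs, self.dropouts, self.dec = [], [], [], []
        cin = cb
        for i, d in enumerate(reversed(range(cfg.depth))):
            cout = f * 2**d
            self.ups.append(UpsampleNearest2())
            self.upconvs.append(_ConvBlock(cin, cout, f"up{d}", rng))
            rate = cfg.dropout_rate if i < cfg.n_dropout_blocks else 0.0
            self.dropouts.append(Dropout(rate))
            self.dec.append(
                (
                    _ConvBlock(cout * 2, cout, f"dec{d}a", rng),
                    _ConvBlock(cout, cout, f"dec{d}b", rng),
                )
            )
            cin = cout
        self.head = Conv2D(cin, cfg.output_channels, 1, name="head", rng=rng)
        self.softmax = SoftmaxChannels()

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> list:
        out = []
        for a, b in self.enc:
            out += a.params() + b.params()
        for blk in self.bottleneck:
            out += blk.params()
        for up, dec_pair in zip(self.upconvs, self.dec):
            out += up.params()
            for blk in dec_pair:
                out += blk.params()
        out += self.head.params()
        return out

    def count_parameters(self) -> tuple[int, int]:
        """(total, trainable); BN moving statistics count as non-trainable."""
        total = sum(p.size for p in self.parameters())
        trainable = sum(p.size for p in self.parameters() if p.trainable)
        return total, trainable

    def set_rng(self, rng) -> None:
        for d in self.dropouts:
            d.rng = rng

    def get_weights(self) -> list:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.parameters(), weights):
            p.value = w.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = np.zeros_like(p.value)

    # -- forward / backward ------------------------------------------------
    def forward(self, x, train: bool = False) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError("expected (N, C, H, W) input")
        if x.shape[2] % (2**self.cfg.depth) or x.shape[3] % (2**self.cfg.depth):
            raise ValueError("spatial size must be divisible by the down-sampling factor")
        skips = []
        h = x
        for (blk_a, blk_b), pool in zip(self.enc, self.pools):
            h = blk_b.forward(blk_a.forward(h, train), train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck[1].forward(self.bottleneck[0].forward(h, train), train)
        for up, upconv, drop, (dec_a, dec_b), skip in zip(
            self.ups, self.upconvs, self.dropouts, self.dec, reversed(skips)
        ):
            h = drop.forward(upconv.forward(up.forward(h, train), train), train)
            h = np.concatenate([h, skip], axis=1)
            h = dec_b.forward(dec_a.forward(h, train), train)
        return self.softmax.forward(self.head.forward(h, train), train)

    def backward(self, grad) -> np.ndarray:
        """Backpropagate dL/d(posterior); returns dL/d(input)."""
        g = self.head.backward(self.softmax.backward(grad))
        skip_grads = []
        for up, upconv, drop, (dec_a, dec_b) in zip(
            reversed(self.ups), reversed(self.upconvs), reversed(self.dropouts), reversed(self.dec)
        ):
            g = dec_a.backward(dec_b.backward(g))
            half = g.shape[1] // 2
            g, g_skip = g[:, :half], g[:, half:]
            skip_grads.append(g_skip)
            g = up.backward(upconv.backward(drop.backward(g)))
        g = self.bottleneck[0].backward(self.bottleneck[1].backward(g))
        for (blk_a, blk_b), pool, g_skip in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g) + g_skip
            g = blk_a.backward(blk_b.backward(g))
        return g


def build_unet(cfg: UNetConfig | None = None) -> tuple[UNet, int, int]:
    """Build the UNet; returns ``(model, total_params, trainable_params)``."""
    cfg = cfg or UNetConfig()
    model = UNet(cfg)
    total, trainable = model.count_parameters()
    return model, total, trainable
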