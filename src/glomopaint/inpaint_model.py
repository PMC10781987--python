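"""The inpainting generator and its two PatchGAN discriminators.

Generator: a 7x7 stem plus two stride-2 convolutions encode the 4-channel
input (RGB gap image + mask) to quarter resolution; eight AOT blocks mix
context at dilation rates (1, 2, 4, 8); a self-attention block (placed where
a 256x256 input has 64x64 features) adds global context; two transposed
convolutions with encoder skip connections decode back to full resolution
and a tanh produces the 3-channel output in [-1, 1].

Discriminators: six 4x4 stride-2 convolutions (channels 64..512, then 1)
map a 256x256 image to a 4x4 grid of patch realism scores.  The global and
local discriminators share this architecture; "local" refers to its input
(the glomerulus on a white canvas), not its wiring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nd import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Module,
    Tensor,
    as_tensor,
    concat,
)
from .nd import serialize

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "AOTBlock",
    "SelfAttention",
    "InpaintGenerator",
    "PatchDiscriminator",
    "build_generator",
    "build_discriminator",
    "save_generator",
    "load_generator",
]

LEAKY_SLOPE = 0.2


@dataclass
class GeneratorConfig:
    input_channels: int = 4
    base_width: int = 64
    n_aot_blocks: int = 8
    aot_dilation_rates: tuple[int, ...] = (1, 2, 4, 8)
    image_size: int = 256
    attention_at: int = 64
    gate_flip: bool = False  # swap which of x1/x2 receives the gate
    seed: int = 0

    def validate(self) -> None:
        if self.n_aot_blocks < 1:
            raise ValueError("need at least one AOT block")
        if self.image_size % 4 != 0:
            raise ValueError("image_size must be divisible by 4")
        if self.attention_at != self.image_size // 4:
            raise ValueError(
                "self-attention must sit at quarter resolution "
                f"({self.image_size // 4}), got {self.attention_at}"
            )
        bottleneck = 4 * self.base_width
        if bottleneck % len(self.aot_dilation_rates) != 0:
            raise ValueError(
                f"bottleneck channels {bottleneck} not divisible by "
                f"{len(self.aot_dilation_rates)} AOT branches"
            )

    def as_dict(self) -> dict:
        return {
            "input_channels": self.input_channels,
            "base_width": self.base_width,
            "n_aot_blocks": self.n_aot_blocks,
            "aot_dilation_rates": list(self.aot_dilation_rates),
            "image_size": self.image_size,
            "attention_at": self.attention_at,
            "gate_flip": self.gate_flip,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["aot_dilation_rates"] = tuple(d.get("aot_dilation_rates", (1, 2, 4, 8)))
        return cls(**d)


@dataclass
class DiscriminatorConfig:
    in_channels: int = 3
    channels: tuple[int, ...] = (64, 128, 256, 512, 512, 1)
    kernel: int = 4
    stride: int = 2
    image_size: int = 256
    batchnorm_first_last: bool = False  # literal Conv+LReLU+BN on every layer
    seed: int = 0

    @property
    def output_size(self) -> int:
        return self.image_size // (self.stride ** len(self.channels))


class _ConvBlock(Module):
    """Conv + (BatchNorm) + LeakyReLU."""

    def __init__(self, in_ch, out_ch, kernel, stride, padding,
                 rng, norm=True, dilation=1):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride=stride,
                           padding=padding, dilation=dilation, rng=rng)
        self.norm = BatchNorm2d(out_ch) if norm else None

    def forward(self, x):
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        return x.leaky_relu(LEAKY_SLOPE)


class AOTBlock(Module):
    """Aggregated contextual transformation block.

    Split the input channels into one branch per dilation rate, transform
    each with a dilated 3x3 convolution, merge by concatenation plus a 3x3
    fusion convolution (the residual feature x2), and gate against the
    input x1 with a spatially varying ``beta = sigmoid(conv(x1))``:
    ``out = beta*x1 + (1-beta)*x2`` (or flipped when configured).
    """

    def __init__(self, channels: int, dilation_rates: tuple[int, ...],
                 rng: np.random.Generator, gate_flip: bool = False):
        super().__init__()
        k = len(dilation_rates)
        if channels % k != 0:
            raise ValueError(
                f"channels {channels} not divisible by {k} branches"
            )
        self.dilation_rates = tuple(dilation_rates)
        self.gate_flip = gate_flip
        self.split = channels // k
        self.branches: list[Conv2d] = []
        for i, d in enumerate(dilation_rates):
            conv = Conv2d(self.split, self.split, 3, padding=d, dilation=d, rng=rng)
            self.add_module(f"branch{i}", conv)
            self.branches.append(conv)
        self.fuse = Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.gate = Conv2d(channels, channels, 3, padding=1, rng=rng)

    def forward(self, x1):
        if x1.shape[1] != self.split * len(self.branches):
            raise ValueError(
                f"expected {self.split * len(self.branches)} channels, "
                f"got {x1.shape[1]}"
            )
        parts = []
        for i, conv in enumerate(self.branches):
            xi = x1[:, i * self.split : (i + 1) * self.split]
            parts.append(conv(xi).leaky_relu(LEAKY_SLOPE))
        x2 = self.fuse(concat(parts, axis=1))
        beta = self.gate(x1).sigmoid()
        if self.gate_flip:
            return (1.0 - beta) * x1 + beta * x2
        return beta * x1 + (1.0 - beta) * x2


class SelfAttention(Module):
    """Non-local self-attention with a zero-initialised residual gain.

    Query/key/value come from 1x1 convolutions; attention rows are softmax
    normalised over all positions; the output is ``x + gamma * attended``
    with gamma starting at 0, so at initialisation the block is an identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        qk = max(1, channels // 8)
        self.query = Conv2d(channels, qk, 1, rng=rng)
        self.key = Conv2d(channels, qk, 1, rng=rng)
        self.value = Conv2d(channels, channels, 1, rng=rng)
        self.register_parameter("gamma", Tensor(np.zeros(1, dtype=np.float32)))

    def attention_weights(self, x) -> Tensor:
        x = as_tensor(x)
        n, c, h, w = x.shape
        q = self.query(x).reshape(n, -1, h * w)
        k = self.key(x).reshape(n, -1, h * w)
        energy = q.transpose(0, 2, 1) @ k  # (n, HW, HW)
        return energy.softmax(axis=-1)

    def forward(self, x):
        x = as_tensor(x)
        n, c, h, w = x.shape
        attn = self.attention_weights(x)
        v = self.value(x).reshape(n, c, h * w)
        out = v @ attn.transpose(0, 2, 1)
        return x + self.gamma * out.reshape(n, c, h, w)


class InpaintGenerator(Module):
    def __init__(self, config: GeneratorConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.base_width
        self.enc0 = _ConvBlock(config.input_channels, w, 7, 1, 3, rng)
        self.enc1 = _ConvBlock(w, 2 * w, 4, 2, 1, rng)
        self.enc2 = _ConvBlock(2 * w, 4 * w, 4, 2, 1, rng)
        self.aot_blocks: list[AOTBlock] = []
        for i in range(config.n_aot_blocks):
            blk = AOTBlock(4 * w, config.aot_dilation_rates, rng,
                           gate_flip=config.gate_flip)
            self.add_module(f"aot{i}", blk)
            self.aot_blocks.append(blk)
        self.attention = SelfAttention(4 * w, rng)
        self.dec1 = ConvTranspose2d(4 * w, 2 * w, 4, stride=2, padding=1, rng=rng)
        self.dec1_norm = BatchNorm2d(2 * w)
        self.skip1 = _ConvBlock(4 * w, 2 * w, 3, 1, 1, rng)
        self.dec2 = ConvTranspose2d(2 * w, w, 4, stride=2, padding=1, rng=rng)
        self.dec2_norm = BatchNorm2d(w)
        self.skip0 = _ConvBlock(2 * w, w, 3, 1, 1, rng)
        self.out_conv = Conv2d(w, 3, 3, padding=1, rng=rng)
        self._attention_input_size: tuple[int, int] | None = None

    def forward(self, x):
        x = as_tensor(x)
        if x.ndim != 4 or x.shape[1] != self.config.input_channels:
            raise ValueError(
                f"expected (N, {self.config.input_channels}, H, W), got {x.shape}"
            )
        e0 = self.enc0(x)
        e1 = self.enc1(e0)
        e2 = self.enc2(e1)
        h = e2
        for blk in self.aot_blocks:
            h = blk(h)
        self._attention_input_size = (h.shape[2], h.shape[3])
        h = self.attention(h)
        d1 = self.dec1_norm(self.dec1(h)).leaky_relu(LEAKY_SLOPE)
        d1 = self.skip1(concat([d1, e1], axis=1))
        d2 = self.dec2_norm(self.dec2(d1)).leaky_relu(LEAKY_SLOPE)
        d2 = self.skip0(concat([d2, e0], axis=1))
        return self.out_conv(d2).tanh()


class PatchDiscriminator(Module):
    def __init__(self, config: DiscriminatorConfig | None = None):
        super().__init__()
        self.config = config or DiscriminatorConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        prev = cfg.in_channels
        self.blocks: list[Module] = []
        n = len(cfg.channels)
        pad = cfg.kernel // 2 - 1  # halving padding for kernel 4 stride 2
        for i, ch in enumerate(cfg.channels):
            first, last = i == 0, i == n - 1
            norm = cfg.batchnorm_first_last or not (first or last)
            if last:
                block = Conv2d(prev, ch, cfg.kernel, stride=cfg.stride,
                               padding=pad, rng=rng)
            else:
                block = _ConvBlock(prev, ch, cfg.kernel, cfg.stride, pad,
                                   rng, norm=norm)
            self.add_module(f"layer{i}", block)
            self.blocks.append(block)
            prev = ch

    def forward(self, x):
        x = as_tensor(x)
        cfg = self.config
        if x.ndim != 4 or x.shape[1] != cfg.in_channels or (
            x.shape[2] != cfg.image_size or x.shape[3] != cfg.image_size
        ):
            raise ValueError(
                f"expected (N, {cfg.in_channels}, {cfg.image_size}, "
                f"{cfg.image_size}), got {x.shape}"
            )
        for block in self.blocks:
            x = block(x)
        return x


def build_generator(config: GeneratorConfig | None = None) -> InpaintGenerator:
    return InpaintGenerator(config or GeneratorConfig())


def build_discriminator(config: DiscriminatorConfig | None = None) -> PatchDiscriminator:
    return PatchDiscriminator(config)


def save_generator(path, gen: InpaintGenerator) -> None:
    serialize.save_checkpoint(path, gen.state_dict(),
                              {"kind": "inpaint_generator", **gen.config.as_dict()})


def load_generator(path) -> InpaintGenerator:
    state, config = serialize.load_checkpoint(path)
    kind = config.pop("kind", None)
    if kind != "inpaint_generator":
        raise ValueError(f"not a generator checkpoint (kind={kind!r})")
    gen = InpaintGenerator(GeneratorConfig.from_dict(config))
    gen.load_state_dict(state)
    return gen
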