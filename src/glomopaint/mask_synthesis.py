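"""Synthesis of novel sclerosed-glomerulus mask shapes.

A DCGAN learns the shape distribution of real glomerulus masks at 64x64
(transposed-conv generator, strided-conv discriminator, non-saturating
losses); samples are bilinearly upsampled to the working resolution and
post-processed: converted to a single channel, binarized, cleaned of small
connected components, and optionally rescaled about each component's
centroid so the final pool covers glomerulus sizes evenly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .nd import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Linear,
    Module,
    Tensor,
)
from .nd import functional as F
from .nd.serialize import load_checkpoint, save_checkpoint
from .types import MaskArtifact

logger = logging.getLogger(__name__)

__all__ = [
    "MaskGANConfig",
    "MaskGenerator",
    "MaskDiscriminator",
    "MaskSampler",
    "train_mask_gan",
    "postprocess_mask",
    "rescale_contours",
    "balance_size_distribution",
    "save_sampler",
    "load_sampler",
]

DEFAULT_MIN_AREA = 200  # px at 256x256
DEFAULT_THRESHOLD = 0.5


@dataclass
class MaskGANConfig:
    latent_dim: int = 64
    image_size: int = 64  # GAN operating resolution (power of two)
    output_size: int = 256  # resolution of emitted masks
    base_width: int = 32
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 16
    epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.image_size & (self.image_size - 1):
            raise ValueError("image_size must be a power of two")

    def as_dict(self) -> dict:
        return {
            "latent_dim": self.latent_dim, "image_size": self.image_size,
            "output_size": self.output_size, "base_width": self.base_width,
            "lr": self.lr, "betas": list(self.betas),
            "batch_size": self.batch_size, "epochs": self.epochs,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaskGANConfig":
        d = dict(d)
        d["betas"] = tuple(d.get("betas", (0.5, 0.999)))
        return cls(**d)


class MaskGenerator(Module):
    """latent -> 4x4 projection -> 4 transposed convs -> sigmoid raster."""

    def __init__(self, config: MaskGANConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.base_width
        self.project = Linear(config.latent_dim, 8 * w * 4 * 4, rng=rng)
        self.project_norm = BatchNorm2d(8 * w)
        chans = [8 * w, 4 * w, 2 * w, w]
        self.ups: list[ConvTranspose2d] = []
        self.norms: list[BatchNorm2d | None] = []
        n_up = int(np.log2(config.image_size // 4))
        outs = chans[1:] + [1] * (n_up - len(chans) + 1)
        prev = chans[0]
        for i in range(n_up):
            out_ch = outs[i] if i < n_up - 1 else 1
            up = ConvTranspose2d(prev, out_ch, 4, stride=2, padding=1, rng=rng)
            self.add_module(f"up{i}", up)
            self.ups.append(up)
            norm = BatchNorm2d(out_ch) if i < n_up - 1 else None
            if norm is not None:
                self.add_module(f"norm{i}", norm)
            self.norms.append(norm)
            prev = out_ch

    def forward(self, z):
        w = self.config.base_width
        h = self.project(z).reshape(z.shape[0], 8 * w, 4, 4)
        h = self.project_norm(h).relu()
        for up, norm in zip(self.ups, self.norms):
            h = up(h)
            if norm is not None:
                h = norm(h).relu()
        return h.sigmoid()


class MaskDiscriminator(Module):
    def __init__(self, config: MaskGANConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed + 7)
        w = config.base_width
        n_down = int(np.log2(config.image_size // 4))
        chans = [w * (2 ** i) for i in range(n_down)]
        prev = 1
        self.convs: list[Conv2d] = []
        self.norms: list[BatchNorm2d | None] = []
        for i, ch in enumerate(chans):
            conv = Conv2d(prev, ch, 4, stride=2, padding=1, rng=rng)
            self.add_module(f"conv{i}", conv)
            self.convs.append(conv)
            norm = BatchNorm2d(ch) if i > 0 else None
            if norm is not None:
                self.add_module(f"dnorm{i}", norm)
            self.norms.append(norm)
            prev = ch
        self.head = Linear(prev * 4 * 4, 1, rng=rng)

    def forward(self, x):
        h = x
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = h.leaky_relu(0.2)
        return self.head(h.reshape(h.shape[0], -1))


class MaskSampler:
    """Maps latent vectors to [0,1] rasters at the configured output size."""

    def __init__(self, generator: MaskGenerator, config: MaskGANConfig):
        self.generator = generator
        self.config = config

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float32).reshape(-1, self.config.latent_dim)
        self.generator.eval()
        out = self.generator(Tensor(z))
        if self.config.output_size != self.config.image_size:
            out = F.upsample_bilinear(
                out, (self.config.output_size, self.config.output_size)
            )
        self.generator.train()
        return out.data[:, 0]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, self.config.latent_dim)).astype(np.float32)
        return self(z)


def _bce_logits(logits: Tensor, target: float) -> Tensor:
    p = logits.sigmoid().clamp(1e-6, 1.0 - 1e-6)
    if target == 1.0:
        return -(p.log()).mean()
    return -((1.0 - p).log()).mean()


def train_mask_gan(
    real_masks: list[np.ndarray],
    config: MaskGANConfig | None = None,
    max_steps: int | None = None,
) -> MaskSampler:
    """Standard DCGAN minimax training on binary mask rasters."""
    config = config or MaskGANConfig()
    if not real_masks:
        raise ValueError("empty training set")
    if len(real_masks) < 2 * config.batch_size:
        raise ValueError(
            f"need >= {2 * config.batch_size} real masks, got {len(real_masks)}"
        )
    from skimage.transform import resize

    s = config.image_size
    data = np.stack(
        [
            resize(np.asarray(m, dtype=float), (s, s), order=1,
                   anti_aliasing=False, preserve_range=True)
            for m in real_masks
        ]
    ).astype(np.float32)[:, None]
    gen = MaskGenerator(config)
    disc = MaskDiscriminator(config)
    g_opt = Adam(gen.parameters(), lr=config.lr, betas=config.betas)
    d_opt = Adam(disc.parameters(), lr=config.lr, betas=config.betas)
    rng = np.random.default_rng(config.seed)
    step = 0
    n = len(data)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for b0 in range(0, n - config.batch_size + 1, config.batch_size):
            idx = order[b0 : b0 + config.batch_size]
            real = Tensor(data[idx])
            z = rng.standard_normal((config.batch_size, config.latent_dim)).astype(np.float32)
            fake = gen(Tensor(z))
            # discriminator: real -> 1, fake -> 0
            d_opt.zero_grad()
            d_loss = _bce_logits(disc(real), 1.0) + _bce_logits(disc(fake.detach()), 0.0)
            d_loss.backward()
            d_opt.step()
            # generator: non-saturating, fake -> 1
            g_opt.zero_grad()
            g_loss = _bce_logits(disc(fake), 1.0)
            g_loss.backward()
            g_opt.step()
            step += 1
            if max_steps is not None and step >= max_steps:
                return MaskSampler(gen, config)
    return MaskSampler(gen, config)


def postprocess_mask(
    raw: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    threshold: float = DEFAULT_THRESHOLD,
) -> MaskArtifact:
    """Grayscale -> binarize -> drop 8-connected components below min_area."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw raster contains non-finite values")
    if raw.ndim == 3:
        raw = 0.299 * raw[..., 0] + 0.587 * raw[..., 1] + 0.114 * raw[..., 2]
    binary = (raw >= threshold).astype(np.uint8)
    labels, n = cc_label(binary, connectivity=2, return_num=True)
    if n:
        areas = np.bincount(labels.ravel())
        drop = np.flatnonzero(areas < min_area)
        binary[np.isin(labels, drop[drop > 0])] = 0
    return MaskArtifact(binary, provenance="postprocessed")


def _rescale_component(
    comp: np.ndarray, factor: float, out_shape: tuple[int, int]
) -> tuple[np.ndarray, bool]:
    """Nearest-neighbour rescale of one component about its own centroid."""
    ys, xs = np.nonzero(comp)
    cy, cx = ys.mean(), xs.mean()
    h, w = out_shape
    half_h = (ys.max() - ys.min()) / 2 * factor + 1
    half_w = (xs.max() - xs.min()) / 2 * factor + 1
    y0, y1 = int(np.floor(cy - half_h)), int(np.ceil(cy + half_h))
    x0, x1 = int(np.floor(cx - half_w)), int(np.ceil(cx + half_w))
    clipped = y0 < 0 or x0 < 0 or y1 >= h or x1 >= w
    y0c, y1c = max(0, y0), min(h - 1, y1)
    x0c, x1c = max(0, x0), min(w - 1, x1)
    yy, xx = np.mgrid[y0c : y1c + 1, x0c : x1c + 1]
    src_y = np.rint(cy + (yy - cy) / factor).astype(int)
    src_x = np.rint(cx + (xx - cx) / factor).astype(int)
    valid = (src_y >= 0) & (src_y < h) & (src_x >= 0) & (src_x < w)
    out = np.zeros(out_shape, dtype=np.uint8)
    hit = np.zeros_like(valid)
    hit[valid] = comp[src_y[valid], src_x[valid]] > 0
    out[y0c : y1c + 1, x0c : x1c + 1] = hit
    return out, clipped


def rescale_contours(mask: MaskArtifact, factor: float) -> MaskArtifact:
    """Scale every foreground component about its centroid by ``factor``."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    if factor == 1.0:
        return MaskArtifact(mask.raster.copy(), provenance="scaled",
                            scale_factor=1.0)
    labels, n = cc_label(mask.raster, connectivity=2, return_num=True)
    out = np.zeros_like(mask.raster)
    for i in range(1, n + 1):
        comp = (labels == i).astype(np.uint8)
        scaled, clipped = _rescale_component(comp, factor, out.shape)
        if clipped:
            logger.warning("rescaled component %d clipped at raster bounds", i)
        out |= scaled
    return MaskArtifact(out, provenance="scaled", scale_factor=factor)


def balance_size_distribution(
    masks: list[MaskArtifact],
    bins: list[tuple[float, float]],
    seed: int = 0,
    min_area: int = DEFAULT_MIN_AREA,
) -> list[MaskArtifact]:
    """Rescale masks between area bins until counts are equal (+-1).

    Surplus masks from overfull bins are rescaled toward a uniformly drawn
    target area inside a deficit bin (factor = sqrt(target/current)).
    """
    if not masks:
        raise ValueError("empty mask list")
    if not bins:
        raise ValueError("empty bin list")
    h, w = masks[0].raster.shape
    for lo, hi in bins:
        if lo >= hi or lo < 0 or lo > h * w:
            raise ValueError(f"unreachable area bin ({lo}, {hi}) for {h}x{w} rasters")
    rng = np.random.default_rng(seed)

    def bin_of(area: float) -> int | None:
        for j, (lo, hi) in enumerate(bins):
            if lo <= area < hi:
                return j
        return None

    k = len(bins)
    n = len(masks)
    base, extra = divmod(n, k)
    targets = [base + (1 if j < extra else 0) for j in range(k)]
    groups: list[list[MaskArtifact]] = [[] for _ in range(k)]
    stray: list[MaskArtifact] = []
    for m in masks:
        j = bin_of(m.area)
        (groups[j] if j is not None else stray).append(m)
    # stray masks count as surplus wherever room remains
    out: list[MaskArtifact] = []
    surplus: list[MaskArtifact] = list(stray)
    for j in range(k):
        keep = groups[j][: targets[j]]
        surplus.extend(groups[j][targets[j] :])
        out.extend(keep)
    for j in range(k):
        have = sum(1 for m in out if bin_of(m.area) == j)
        while have < targets[j] and surplus:
            m = surplus.pop()
            lo, hi = bins[j]
            target_area = rng.uniform(max(lo, min_area), hi)
            if m.area <= 0:
                continue
            factor = float(np.sqrt(target_area / m.area))
            scaled = rescale_contours(m, factor)
            if bin_of(scaled.area) != j:
                # rasterization error pushed it out; nudge to the bin centre
                factor = float(np.sqrt(((lo + hi) / 2) / m.area))
                scaled = rescale_contours(m, factor)
            out.append(scaled)
            have += 1
    return out


def save_sampler(path, sampler: MaskSampler) -> None:
    save_checkpoint(path, sampler.generator.state_dict(),
                    {"kind": "mask_gan", **sampler.config.as_dict()})


def load_sampler(path) -> MaskSampler:
    state, config = load_checkpoint(path)
    if config.pop("kind", None) != "mask_gan":
        raise ValueError("not a mask GAN checkpoint")
    cfg = MaskGANConfig.from_dict(config)
    gen = MaskGenerator(cfg)
    gen.load_state_dict(state)
    return MaskSampler(gen, cfg)
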