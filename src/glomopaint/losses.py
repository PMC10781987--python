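"""Loss functions for the inpainting GAN and the segmentation network.

The inpainter's objective balances global fidelity against fidelity inside
the glomerulus ("attention" on the inpainted object):

* least-squares adversarial terms from a global discriminator (whole image)
  and a local discriminator (glomerulus on a white canvas),
* global and local pixel L1,
* perceptual and style (Gram) distances under a frozen feature extractor,

combined as  ``L = lam_adv*(L_advg + L_advl) + lam_1g*L1g + lam_1l*L1l +
lam_per*L_per + lam_sty*L_sty`` with defaults (0.02, 1, 1, 0.1, 150).

All functions accept ``nd.Tensor`` or numpy arrays in NCHW layout with
values in [0, 1]; masks are single-channel {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nd import Module, Tensor, as_tensor, concat
from .nd.layers import Conv2d
from .types import LossReport

__all__ = [
    "LossWeights",
    "make_inpaint_input",
    "local_region",
    "adversarial_losses",
    "generator_adversarial",
    "l1_losses",
    "gram_matrix",
    "perceptual_and_style",
    "total_inpaint_loss",
    "seg_loss",
    "IdentityFeatures",
    "RandomConvFeatures",
]


@dataclass
class LossWeights:
    adv: float = 0.02
    l1_g: float = 1.0
    l1_l: float = 1.0
    perceptual: float = 0.1
    style: float = 150.0
    seg_lambda: float = 0.5

    def __post_init__(self):
        for name in ("adv", "l1_g", "l1_l", "perceptual", "style", "seg_lambda"):
            if getattr(self, name) < 0:
                raise ValueError(f"loss weight {name} must be nonnegative")


def _binary(mask: Tensor) -> Tensor:
    vals = np.unique(mask.data)
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise ValueError("mask must be binary {0,1}")
    return mask


def make_inpaint_input(x_ori, x_mask) -> tuple[Tensor, Tensor]:
    """Blank out the glomerulus and stack the mask as a fourth channel.

    ``x_gap = x_ori * (1 - mask)``; ``x_input = concat(x_gap, mask)``.
    """
    x_ori = as_tensor(x_ori)
    x_mask = _binary(as_tensor(x_mask))
    if x_ori.shape[-2:] != x_mask.shape[-2:] or x_ori.ndim != x_mask.ndim:
        raise ValueError(
            f"shape mismatch: image {x_ori.shape} vs mask {x_mask.shape}"
        )
    x_gap = x_ori * (1.0 - x_mask)
    x_input = concat([x_gap, x_mask], axis=-3)
    return x_gap, x_input


def local_region(x, x_mask) -> Tensor:
    """Keep the glomerulus, paint everything else white: ``x*m + (1-m)``."""
    x = as_tensor(x)
    x_mask = as_tensor(x_mask)
    return x * x_mask + (1.0 - x_mask)


def adversarial_losses(d_scores_real, d_scores_fake) -> tuple[Tensor, Tensor]:
    """Least-squares GAN objectives from patch score maps.

    Discriminator: ``E[D(fake)^2] + E[(1 - D(real))^2]`` (expectation over
    patches and batch).  Generator term: ``E[(1 - D(fake))^2]``.
    """
    real = as_tensor(d_scores_real)
    fake = as_tensor(d_scores_fake)
    if real.shape != fake.shape:
        raise ValueError("score maps must have the same shape")
    d_loss = (fake ** 2).mean() + ((1.0 - real) ** 2).mean()
    g_term = ((1.0 - fake) ** 2).mean()
    return d_loss, g_term


def generator_adversarial(d_scores_fake) -> Tensor:
    return ((1.0 - as_tensor(d_scores_fake)) ** 2).mean()


def l1_losses(x_ori, x_rec, x_mask) -> tuple[Tensor, Tensor]:
    """Global and local (white-canvas) mean absolute pixel errors."""
    x_ori = as_tensor(x_ori)
    x_rec = as_tensor(x_rec)
    l1_g = (x_ori - x_rec).abs().mean()
    r_ori = local_region(x_ori, x_mask)
    r_rec = local_region(x_rec, x_mask)
    l1_l = (r_ori - r_rec).abs().mean()
    return l1_g, l1_l


def gram_matrix(feat) -> Tensor:
    """Raw Gram matrix phi^T phi over spatial positions: (N, C, H, W) -> (N, C, C)."""
    feat = as_tensor(feat)
    n, c, h, w = feat.shape
    f = feat.reshape(n, c, h * w)
    return f @ f.transpose(0, 2, 1)


class IdentityFeatures(Module):
    """Test double for the pretrained extractor: one layer, the image itself."""

    layer_names = ("identity",)

    def forward(self, x) -> list[Tensor]:
        return [as_tensor(x)]


class RandomConvFeatures(Module):
    """A frozen random-weight convolutional feature stack.

    Random convolutional features preserve perceptual structure well enough
    to serve as the phi of perceptual/style distances when no pretrained
    backbone is shipped; weights are fixed by seed and never trained.
    """

    def __init__(self, in_ch: int = 3, widths: tuple[int, ...] = (16, 32, 64),
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.convs: list[Conv2d] = []
        prev = in_ch
        for i, w in enumerate(widths):
            conv = Conv2d(prev, w, kernel=3, stride=2, padding=1, rng=rng)
            conv.weight.requires_grad = False
            conv.bias.requires_grad = False
            self.add_module(f"conv{i}", conv)
            self.convs.append(conv)
            prev = w
        self.layer_names = tuple(f"conv{i}_relu" for i in range(len(widths)))

    def forward(self, x) -> list[Tensor]:
        feats = []
        h = as_tensor(x)
        for conv in self.convs:
            h = conv(h).leaky_relu(0.2)
            feats.append(h)
        return feats


def perceptual_and_style(
    x_ori, x_rec, phi: Module, layers: list[str] | None = None
) -> tuple[Tensor, Tensor, list[float], list[float]]:
    """Feature-space distances under a frozen extractor ``phi``.

    ``L_per``: sum over layers of ||phi_i(a) - phi_i(b)||_1 / N_i (N_i =
    element count of the activation).  ``L_sty``: mean over layers of the L1
    distance between raw Gram matrices, normalised by N_i.
    """
    available = list(getattr(phi, "layer_names", ()))
    if layers is None:
        layers = available
    if not layers:
        raise ValueError("layer list must be nonempty")
    unknown = [l for l in layers if l not in available]
    if unknown:
        raise ValueError(f"layers {unknown} not in extractor {available}")
    idx = [available.index(l) for l in layers]
    fa = phi(as_tensor(x_ori))
    fb = phi(as_tensor(x_rec))
    per_layer_p: list[Tensor] = []
    per_layer_s: list[Tensor] = []
    for i in idx:
        n_i = float(fa[i].size)
        per_layer_p.append((fa[i] - fb[i]).abs().sum() * (1.0 / n_i))
        ga, gb = gram_matrix(fa[i]), gram_matrix(fb[i])
        per_layer_s.append((ga - gb).abs().sum() * (1.0 / n_i))
    l_per = per_layer_p[0]
    for t in per_layer_p[1:]:
        l_per = l_per + t
    l_sty = per_layer_s[0]
    for t in per_layer_s[1:]:
        l_sty = l_sty + t
    l_sty = l_sty * (1.0 / len(per_layer_s))
    return (
        l_per,
        l_sty,
        [float(t.item()) for t in per_layer_p],
        [float(t.item()) for t in per_layer_s],
    )


def total_inpaint_loss(
    adv_g: float | Tensor,
    adv_l: float | Tensor,
    l1_g: float | Tensor,
    l1_l: float | Tensor,
    perceptual: float | Tensor,
    style: float | Tensor,
    weights: LossWeights | None = None,
):
    """Exact weighted sum of the six components (generator objective)."""
    w = weights or LossWeights()
    comps = dict(adv_g=adv_g, adv_l=adv_l, l1_g=l1_g, l1_l=l1_l,
                 perceptual=perceptual, style=style)
    for name, v in comps.items():
        val = v.item() if isinstance(v, Tensor) else float(v)
        if not np.isfinite(val):
            raise ValueError(f"loss component {name} is not finite")
        if val < 0:
            raise ValueError(f"loss component {name} is negative ({val})")
    return (
        w.adv * (adv_g + adv_l)
        + w.l1_g * l1_g
        + w.l1_l * l1_l
        + w.perceptual * perceptual
        + w.style * style
    )


def build_loss_report(
    adv_g, adv_l, l1_g, l1_l, perceptual, style,
    weights: LossWeights | None = None,
    per_layer_perceptual: list[float] = (),
    per_layer_style: list[float] = (),
    disc_g: float = 0.0,
    disc_l: float = 0.0,
) -> LossReport:
    def f(v):
        return float(v.item()) if isinstance(v, Tensor) else float(v)

    total = total_inpaint_loss(f(adv_g), f(adv_l), f(l1_g), f(l1_l),
                               f(perceptual), f(style), weights)
    return LossReport(
        adv_g=f(adv_g), adv_l=f(adv_l), l1_g=f(l1_g), l1_l=f(l1_l),
        perceptual=f(perceptual), style=f(style), total=float(total),
        per_layer_perceptual=list(per_layer_perceptual),
        per_layer_style=list(per_layer_style),
        disc_g=f(disc_g), disc_l=f(disc_l),
    )


def seg_loss(pred, target, lam: float = 0.5, eps: float = 1e-6) -> Tensor:
    """Segmentation objective: ``lam * BCE + soft-Dice loss``.

    Soft Dice loss is ``1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)``
    pooled over the whole batch.
    """
    pred = as_tensor(pred)
    target = as_tensor(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = pred.clamp(eps, 1.0 - eps)
    bce = -(target * p.log() + (1.0 - target) * (1.0 - p).log()).mean()
    inter = (p * target).sum()
    dice = 1.0 - (2.0 * inter + eps) / (p.sum() + target.sum() + eps)
    return lam * bce + dice
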