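"""Adversarial training loop for the inpainting network.

Training alternates one discriminator step (least-squares objective on the
global image and on the white-canvas local glomerulus) with one generator
step (the weighted attention loss).  Defaults follow the study conditions:
Adam, lr 1e-4, betas (0.5, 0.999), batch 16, 100 epochs, train/test split
8:2.  With ``weights.adv == 0`` the discriminators are never touched and
the loop is a deterministic minimisation of the non-adversarial terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import losses as L
from . import metrics as M
from .inpaint_model import (
    DiscriminatorConfig,
    InpaintGenerator,
    PatchDiscriminator,
)
from .nd import Adam, Tensor
from .nd.serialize import save_checkpoint
from .types import GlomCrop, ImageQuality, LossReport, MetricsReport

__all__ = [
    "InpaintTrainConfig",
    "split_dataset",
    "crops_to_arrays",
    "train_inpainter",
    "evaluate_inpainter",
]


@dataclass
class InpaintTrainConfig:
    lr: float = 1e-4
    betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 16
    epochs: int = 100
    seed: int = 0


def split_dataset(
    crops: list, ratio: float = 0.8, seed: int = 0
) -> tuple[list, list]:
    """Reproducible disjoint train/test split; train size = round(ratio*n)."""
    n = len(crops)
    if n < 2:
        raise ValueError("need at least 2 crops to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    train = [crops[i] for i in order[:n_train]]
    test = [crops[i] for i in order[n_train:]]
    return train, test


def crops_to_arrays(crops: list[GlomCrop]) -> tuple[np.ndarray, np.ndarray]:
    """Stack crops to NCHW float arrays: images in [0,1], masks {0,1}."""
    imgs = np.stack([c.image for c in crops]).astype(np.float32) / 255.0
    masks = np.stack([c.mask for c in crops]).astype(np.float32)
    return imgs.transpose(0, 3, 1, 2), masks[:, None]


def _generator_input(x_ori: np.ndarray, x_mask: np.ndarray) -> Tensor:
    """Network input: the gap image scaled to [-1,1] plus the 0/1 mask channel."""
    x_gap_n = (2.0 * x_ori - 1.0) * (1.0 - x_mask)
    return Tensor(np.concatenate([x_gap_n, x_mask], axis=1))


def _forward_losses(
    gen: InpaintGenerator,
    disc_g: PatchDiscriminator | None,
    disc_l: PatchDiscriminator | None,
    x_ori: np.ndarray,
    x_mask: np.ndarray,
    weights: L.LossWeights,
    phi,
) -> tuple[Tensor, LossReport, Tensor]:
    x_in = _generator_input(x_ori, x_mask)
    x_rec = (gen(x_in) + 1.0) * 0.5  # back to [0,1] for all losses
    ori_t = Tensor(x_ori)
    mask_t = Tensor(x_mask)
    l1_g, l1_l = L.l1_losses(ori_t, x_rec, mask_t)
    l_per, l_sty, plp, pls = L.perceptual_and_style(ori_t, x_rec, phi)
    if weights.adv > 0 and disc_g is not None:
        adv_g = L.generator_adversarial(disc_g(x_rec))
        r_rec = L.local_region(x_rec, mask_t)
        adv_l = L.generator_adversarial(disc_l(r_rec))
    else:
        adv_g = Tensor(0.0)
        adv_l = Tensor(0.0)
    total = L.total_inpaint_loss(adv_g, adv_l, l1_g, l1_l, l_per, l_sty, weights)
    report = L.build_loss_report(
        adv_g, adv_l, l1_g, l1_l, l_per, l_sty, weights,
        per_layer_perceptual=plp, per_layer_style=pls,
    )
    return total, report, x_rec


def train_inpainter(
    train_crops: list[GlomCrop],
    generator: InpaintGenerator,
    discriminators: tuple[PatchDiscriminator, PatchDiscriminator] | None = None,
    weights: L.LossWeights | None = None,
    config: InpaintTrainConfig | None = None,
    phi=None,
    out_dir=None,
    max_steps: int | None = None,
    resume_state: dict | None = None,
) -> tuple[list[LossReport], dict]:
    """Train the generator (and discriminators when ``weights.adv > 0``).

    Returns the per-G-step loss log and a resumable state dict (optimiser
    moments and epoch counter).  ``max_steps`` caps the total number of
    generator steps, for smoke-scale runs.  Aborts on non-finite loss.
    """
    if not train_crops:
        raise ValueError("empty training set")
    weights = weights or L.LossWeights()
    config = config or InpaintTrainConfig()
    phi = phi or L.IdentityFeatures()
    use_gan = weights.adv > 0
    if use_gan:
        if discriminators is None:
            size = generator.config.image_size
            discriminators = (
                PatchDiscriminator(DiscriminatorConfig(image_size=size, seed=config.seed)),
                PatchDiscriminator(DiscriminatorConfig(image_size=size, seed=config.seed + 1)),
            )
        disc_g, disc_l = discriminators
    else:
        disc_g = disc_l = None

    g_opt = Adam(generator.parameters(), lr=config.lr, betas=config.betas)
    d_opt = None
    if use_gan:
        d_opt = Adam(disc_g.parameters() + disc_l.parameters(),
                     lr=config.lr, betas=config.betas)
    start_epoch = 0
    if resume_state is not None:
        g_opt.load_state_dict(resume_state["g_opt"])
        if d_opt is not None and resume_state.get("d_opt") is not None:
            d_opt.load_state_dict(resume_state["d_opt"])
        start_epoch = int(resume_state["epoch"])

    x_all, m_all = crops_to_arrays(train_crops)
    n = len(train_crops)
    log: list[LossReport] = []
    log_fh = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_fh = open(out_dir / "train_log.jsonl", "a")
    step = 0
    try:
        for epoch in range(start_epoch, config.epochs):
            order = np.random.default_rng(config.seed + 1000 * epoch).permutation(n)
            for b0 in range(0, n, config.batch_size):
                idx = order[b0 : b0 + config.batch_size]
                x_ori, x_mask = x_all[idx], m_all[idx]
                if use_gan:
                    # discriminator step on detached reconstructions
                    generator.eval()
                    x_rec = ((generator(_generator_input(x_ori, x_mask)) + 1.0) * 0.5).detach()
                    generator.train()
                    d_opt.zero_grad()
                    dg_loss, _ = L.adversarial_losses(
                        disc_g(Tensor(x_ori)), disc_g(x_rec)
                    )
                    r_ori = L.local_region(Tensor(x_ori), Tensor(x_mask))
                    r_rec = L.local_region(x_rec, Tensor(x_mask))
                    dl_loss, _ = L.adversarial_losses(disc_l(r_ori), disc_l(r_rec))
                    d_total = dg_loss + dl_loss
                    d_total.backward()
                    d_opt.step()
                # generator step
                g_opt.zero_grad()
                total, report, _ = _forward_losses(
                    generator, disc_g, disc_l, x_ori, x_mask, weights, phi
                )
                if use_gan:
                    report.disc_g = float(dg_loss.item())
                    report.disc_l = float(dl_loss.item())
                if not np.isfinite(report.total):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, step {step}: "
                        f"{report.as_dict()}"
                    )
                total.backward()
                g_opt.step()
                log.append(report)
                if log_fh is not None:
                    log_fh.write(json.dumps({"epoch": epoch, "step": step,
                                             **report.as_dict()}) + "\n")
                step += 1
                if max_steps is not None and step >= max_steps:
                    raise StopIteration
            if out_dir is not None:
                save_checkpoint(
                    out_dir / f"epoch_{epoch:04d}.npz",
                    generator.state_dict(),
                    {"kind": "inpaint_generator", **generator.config.as_dict()},
                )
    except StopIteration:
        pass
    finally:
        if log_fh is not None:
            log_fh.close()
    state = {
        "epoch": config.epochs,
        "g_opt": g_opt.state_dict(),
        "d_opt": d_opt.state_dict() if d_opt is not None else None,
    }
    return log, state


def evaluate_inpainter(
    test_crops: list[GlomCrop], generator: InpaintGenerator, batch_size: int = 8
) -> MetricsReport:
    """MAE/PSNR/SSIM of reconstructions, full-image and masked-region."""
    if not test_crops:
        raise ValueError("empty test set")
    was_training = generator.training
    generator.eval()
    x_all, m_all = crops_to_arrays(test_crops)
    full, masked = [], []
    for b0 in range(0, len(test_crops), batch_size):
        x_ori, x_mask = x_all[b0 : b0 + batch_size], m_all[b0 : b0 + batch_size]
        x_rec = ((generator(_generator_input(x_ori, x_mask)) + 1.0) * 0.5).data
        for i in range(len(x_ori)):
            a = x_ori[i].transpose(1, 2, 0)
            b = np.clip(x_rec[i].transpose(1, 2, 0), 0.0, 1.0)
            m = m_all[b0 + i, 0] > 0.5
            full.append(M.image_quality(a, b))
            masked.append(M.image_quality(a, b, mask=m))
    generator.train(was_training)

    def _mean(items: list[ImageQuality], region: str) -> ImageQuality:
        return ImageQuality(
            float(np.mean([q.mae for q in items])),
            float(np.mean([q.psnr for q in items])),
            float(np.mean([q.ssim for q in items])),
            region=region,
        )

    return MetricsReport(image_quality={
        "full": _mean(full, "full"),
        "masked": _mean(masked, "masked"),
    })
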