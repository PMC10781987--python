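"""Encoder–decoder glomerular segmentation.

A staged convolutional encoder feeds a U-shaped decoder; each encoder stage
contributes one skip connection that is concatenated with the upsampled
decoder features at matching resolution.  The output is a two-channel
sigmoid map — one independent channel per class (normal, sclerosed) with an
implicit background, matching the two separate per-class masks the rest of
the pipeline uses.  The ``efficientnet-b3-like`` preset mirrors the stage
count and widths of the EfficientNet-B3 feature pyramid; ``tiny`` is a
three-stage preset for desk-scale training.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import metrics as M
from .losses import seg_loss
from .nd import (
    Adam,
    BatchNorm2d,
    Conv2d,
    CosineAnnealingLR,
    Module,
    Tensor,
    concat,
)
from .nd import functional as F
from .nd.serialize import load_checkpoint, save_checkpoint
from .slide_prep import _axis_starts
from .types import NORMAL, SCLEROSED


__all__ = [
    "SegSample",
    "SegTrainConfig",
    "BACKBONES",
    "build_seg_model",
    "SegModel",
    "traditional_augment",
    "train_segmenter",
    "predict_slide",
    "save_segmenter",
    "load_segmenter",
]

# encoder stage widths per backbone preset; every stage halves resolution
BACKBONES: dict[str, tuple[int, ...]] = {
    "tiny": (8, 16, 32),
    "efficientnet-b3-like": (24, 32, 48, 96, 136),
}


@dataclass
class SegSample:
    """One training tile: RGB image and a 2-channel (normal, sclerosed) target."""

    image: np.ndarray  # (H, W, 3) uint8
    target: np.ndarray  # (2, H, W) {0,1}

    def __post_init__(self):
        if self.target.shape[0] != 2:
            raise ValueError("target must be (2, H, W)")
        if np.any((self.target[0] > 0) & (self.target[1] > 0)):
            raise ValueError("class channels must be mutually exclusive")


@dataclass
class SegTrainConfig:
    backbone: str = "efficientnet-b3-like"
    batch_size: int = 8
    lr: float = 1e-3
    min_lr: float = 1e-5
    epochs: int = 200
    val_ratio: float = 0.2
    lam: float = 0.5
    trad_aug: bool = True
    p_flip: float = 0.5
    p_rot: float = 0.5
    seed: int = 0


class _Block(Module):
    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng)
        self.norm = BatchNorm2d(out_ch)

    def forward(self, x):
        return self.norm(self.conv(x)).leaky_relu(0.1)


class SegModel(Module):
    def __init__(self, backbone: str = "efficientnet-b3-like", seed: int = 0):
        super().__init__()
        if backbone not in BACKBONES:
            raise ValueError(
                f"unknown backbone {backbone!r}; registry: {sorted(BACKBONES)}"
            )
        self.backbone = backbone
        widths = BACKBONES[backbone]
        rng = np.random.default_rng(seed)
        self.enc_stages: list[Module] = []
        prev = 3
        for i, w in enumerate(widths):
            stage = _Block(prev, w, stride=2, rng=rng)
            self.add_module(f"enc{i}", stage)
            self.enc_stages.append(stage)
            prev = w
        self.dec_stages: list[Module] = []
        for i in range(len(widths) - 1, 0, -1):
            # upsampled deep features + skip from the shallower stage
            blk = _Block(widths[i] + widths[i - 1], widths[i - 1], stride=1, rng=rng)
            self.add_module(f"dec{i}", blk)
            self.dec_stages.append(blk)
        self.head_block = _Block(widths[0], widths[0], stride=1, rng=rng)
        self.head = Conv2d(widths[0], 2, 1, rng=rng)
        self.register_buffer("norm_mean", np.full(3, 0.5, dtype=np.float32))
        self.register_buffer("norm_std", np.full(3, 0.25, dtype=np.float32))

    @property
    def n_skips(self) -> int:
        """One skip per encoder stage: the deepest feeds the decoder directly,
        the rest arrive by concatenation."""
        return len(self.enc_stages)

    def encoder_features(self, x) -> list[Tensor]:
        feats = []
        h = x
        for stage in self.enc_stages:
            h = stage(h)
            feats.append(h)
        return feats

    def forward(self, x):
        x = Tensor(x) if isinstance(x, np.ndarray) else x
        feats = self.encoder_features(x)
        h = feats[-1]
        for blk, skip in zip(self.dec_stages, feats[-2::-1]):
            h = F.upsample_nearest(h, 2)
            h = blk(concat([h, skip], axis=1))
        h = F.upsample_nearest(h, 2)  # back to input resolution
        return self.head(self.head_block(h)).sigmoid()

    def normalize(self, images: np.ndarray) -> np.ndarray:
        """uint8 NHWC -> normalized float NCHW using the stored statistics."""
        x = images.astype(np.float32) / 255.0
        x = (x - self.norm_mean) / self.norm_std
        return x.transpose(0, 3, 1, 2)


def build_seg_model(backbone: str = "efficientnet-b3-like", seed: int = 0) -> SegModel:
    return SegModel(backbone, seed=seed)


def traditional_augment(
    sample: SegSample, p_flip: float = 0.5, p_rot: float = 0.5,
    rng: np.random.Generator | None = None, seed: int = 0,
) -> SegSample:
    """Online flip/rot90 augmentation applied identically to image and target."""
    if not (0 <= p_flip <= 1 and 0 <= p_rot <= 1):
        raise ValueError("probabilities must be in [0, 1]")
    rng = rng or np.random.default_rng(seed)
    img = sample.image
    tgt = sample.target
    if rng.random() < p_flip:
        if rng.random() < 0.5:
            img, tgt = img[:, ::-1], tgt[:, :, ::-1]
        else:
            img, tgt = img[::-1], tgt[:, ::-1]
    if rng.random() < p_rot:
        k = int(rng.integers(1, 4))
        img = np.rot90(img, k, axes=(0, 1))
        tgt = np.rot90(tgt, k, axes=(1, 2))
    return SegSample(np.ascontiguousarray(img), np.ascontiguousarray(tgt))


def _dice(pred: np.ndarray, true: np.ndarray) -> float:
    return M.confusion_metrics(pred, true).dice


def _epoch_dice(model: SegModel, samples: list[SegSample], batch: int) -> dict:
    was_training = model.training
    model.eval()
    preds, trues = [], []
    for b0 in range(0, len(samples), batch):
        chunk = samples[b0 : b0 + batch]
        x = model.normalize(np.stack([s.image for s in chunk]))
        p = model(Tensor(x)).data > 0.5
        preds.append(p)
        trues.append(np.stack([s.target for s in chunk]) > 0)
    model.train(was_training)
    p = np.concatenate(preds)
    t = np.concatenate(trues)
    return {
        NORMAL: _dice(p[:, 0], t[:, 0]),
        SCLEROSED: _dice(p[:, 1], t[:, 1]),
    }


def train_segmenter(
    samples: list[SegSample],
    config: SegTrainConfig | None = None,
    model: SegModel | None = None,
    out_dir=None,
) -> tuple[SegModel, list[dict]]:
    """Train with the combined BCE+Dice objective and cosine-annealed Adam.

    Per epoch the history logs mean training loss and per-class Dice on the
    training and (when ``val_ratio > 0``) validation splits.  The
    best-validation checkpoint (highest mean validation Dice) and the last
    checkpoint are both written when ``out_dir`` is given.
    """
    config = config or SegTrainConfig()
    if not samples:
        raise ValueError("empty training manifest")
    rng = np.random.default_rng(config.seed)
    if config.val_ratio > 0 and len(samples) >= 2:
        order = rng.permutation(len(samples))
        n_train = max(1, int(round((1 - config.val_ratio) * len(samples))))
        n_train = min(n_train, len(samples) - 1)
        train = [samples[i] for i in order[:n_train]]
        val = [samples[i] for i in order[n_train:]]
    else:
        train, val = list(samples), []
    if model is None:
        model = SegModel(config.backbone, seed=config.seed)
    mean = np.mean([s.image.reshape(-1, 3) for s in train], axis=(0, 1)) / 255.0
    std = np.std(
        np.concatenate([s.image.reshape(-1, 3) for s in train]), axis=0
    ) / 255.0
    model.norm_mean[...] = mean.astype(np.float32)
    model.norm_std[...] = np.maximum(std, 1e-3).astype(np.float32)

    opt = Adam(model.parameters(), lr=config.lr, betas=(0.9, 0.999))
    sched = CosineAnnealingLR(opt, t_max=config.epochs, lr_min=config.min_lr)
    history: list[dict] = []
    best_val = -1.0
    out_dir = Path(out_dir) if out_dir is not None else None
    for epoch in range(config.epochs):
        losses = []
        order = rng.permutation(len(train))
        for b0 in range(0, len(train), config.batch_size):
            chunk = [train[i] for i in order[b0 : b0 + config.batch_size]]
            if config.trad_aug:
                chunk = [
                    traditional_augment(s, config.p_flip, config.p_rot, rng=rng)
                    for s in chunk
                ]
            x = model.normalize(np.stack([s.image for s in chunk]))
            y = np.stack([s.target for s in chunk]).astype(np.float32)
            opt.zero_grad()
            pred = model(Tensor(x))
            loss = seg_loss(pred, Tensor(y), lam=config.lam)
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        sched.step()
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
            "train_dice": _epoch_dice(model, train, config.batch_size),
        }
        if val:
            entry["val_dice"] = _epoch_dice(model, val, config.batch_size)
            mean_val = float(np.mean(list(entry["val_dice"].values())))
            if mean_val > best_val:
                best_val = mean_val
                if out_dir is not None:
                    save_segmenter(out_dir / "best.npz", model)
        history.append(entry)
    if out_dir is not None:
        save_segmenter(out_dir / "last.npz", model)
        if not val:
            save_segmenter(out_dir / "best.npz", model)
    return model, history


def predict_slide(
    model: SegModel,
    slide: np.ndarray,
    window: int = 1024,
    stride: int = 512,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Tiled inference with probability averaging in overlaps.

    Returns (mask_normal, mask_sclerosed) as {0,1} rasters of the slide's
    size.  Where both class probabilities clear the threshold the pixel is
    resolved by argmax, with sclerosed winning exact ties.
    """
    h, w = slide.shape[:2]
    ph, pw = max(0, window - h), max(0, window - w)
    padded = np.pad(slide, ((0, ph), (0, pw), (0, 0)), mode="reflect") if (ph or pw) else slide
    hp, wp = padded.shape[:2]
    prob = np.zeros((2, hp, wp), dtype=np.float64)
    count = np.zeros((hp, wp), dtype=np.float64)
    was_training = model.training
    model.eval()
    for y in _axis_starts(hp, window, stride):
        for x in _axis_starts(wp, window, stride):
            tile = padded[y : y + window, x : x + window]
            p = model(Tensor(model.normalize(tile[None]))).data[0]
            prob[:, y : y + window, x : x + window] += p
            count[y : y + window, x : x + window] += 1.0
    model.train(was_training)
    prob /= count
    prob = prob[:, :h, :w]
    hit = prob > threshold
    both = hit[0] & hit[1]
    # sclerosed wins ties, consistent with mask rasterization
    sclerosed_wins = prob[1] >= prob[0]
    mask_n = (hit[0] & ~(both & sclerosed_wins)).astype(np.uint8)
    mask_s = (hit[1] & ~(both & ~sclerosed_wins)).astype(np.uint8)
    return mask_n, mask_s


def save_segmenter(path, model: SegModel) -> None:
    save_checkpoint(path, model.state_dict(),
                    {"kind": "segmenter", "backbone": model.backbone})


def load_segmenter(path) -> SegModel:
    state, config = load_checkpoint(path)
    if config.pop("kind", None) != "segmenter":
        raise ValueError("not a segmenter checkpoint")
    model = SegModel(config["backbone"])
    model.load_state_dict(state)
    return model
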