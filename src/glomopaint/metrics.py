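"""Pixel-level segmentation metrics and image-quality metrics.

Confusion-count metrics (precision, recall, F1, Dice) follow the usual
pixelwise definitions; F1 and Dice computed from the same counts are the
same algebraic quantity and are reported separately only because published
tables list both.  Image quality between an original and a reconstruction
uses MAE, PSNR (dB, peak 1.0) and SSIM (11x11 Gaussian window, sigma 1.5).
"""

from __future__ import annotations

import numpy as np

from .types import ClassMetrics, ImageQuality

__all__ = [
    "confusion_counts",
    "confusion_metrics",
    "aggregate_confusion",
    "mae",
    "psnr",
    "ssim",
    "image_quality",
]

_SSIM_K1 = 0.01
_SSIM_K2 = 0.03
_SSIM_WIN = 11
_SSIM_SIGMA = 1.5


def confusion_counts(pred: np.ndarray, true: np.ndarray) -> tuple[int, int, int, int]:
    pred = np.asarray(pred).astype(bool)
    true = np.asarray(true).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    return tp, fp, fn, tn


def _metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> ClassMetrics:
    # 0/0 -> 0 by convention; both masks empty -> trivial perfect agreement
    if tp == 0 and fp == 0 and fn == 0:
        val = 1.0
        return ClassMetrics(tp, fp, fn, tn, val, val, val, val)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    dice = 2.0 * tp / (fp + 2.0 * tp + fn)
    return ClassMetrics(tp, fp, fn, tn, precision, recall, f1, dice)


def confusion_metrics(pred: np.ndarray, true: np.ndarray) -> ClassMetrics:
    """Precision, recall, F1 and Dice from two binary rasters."""
    return _metrics_from_counts(*confusion_counts(pred, true))


def aggregate_confusion(
    pairs: list[tuple[np.ndarray, np.ndarray]], mode: str = "micro"
) -> ClassMetrics:
    """Aggregate over slides: pool pixel counts (micro) or average (macro)."""
    if mode == "micro":
        tot = np.zeros(4, dtype=np.int64)
        for p, t in pairs:
            tot += np.asarray(confusion_counts(p, t))
        return _metrics_from_counts(*tot.tolist())
    if mode == "macro":
        ms = [confusion_metrics(p, t) for p, t in pairs]
        tot = np.sum([[m.tp, m.fp, m.fn, m.tn] for m in ms], axis=0)
        return ClassMetrics(
            *[int(v) for v in tot],
            float(np.mean([m.precision for m in ms])),
            float(np.mean([m.recall for m in ms])),
            float(np.mean([m.f1 for m in ms])),
            float(np.mean([m.dice for m in ms])),
        )
    raise ValueError(f"unknown aggregation mode {mode!r}")


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mae(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    a, b = _check_pair(a, b)
    diff = np.abs(a - b)
    if mask is not None:
        sel = np.asarray(mask).astype(bool)
        if sel.ndim == a.ndim - 1:
            sel = np.broadcast_to(sel[..., None], a.shape)
        diff = diff[sel]
    return float(diff.mean())


def psnr(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None,
         max_val: float = 1.0) -> float:
    """PSNR in dB; identical inputs return ``inf`` rather than raising."""
    a, b = _check_pair(a, b)
    diff = (a - b) ** 2
    if mask is not None:
        sel = np.asarray(mask).astype(bool)
        if sel.ndim == a.ndim - 1:
            sel = np.broadcast_to(sel[..., None], a.shape)
        diff = diff[sel]
    mse = float(diff.mean())
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_val ** 2 / mse))


def _gaussian_kernel(win: int, sigma: float) -> np.ndarray:
    r = win // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    k2 = np.outer(k, k)
    return k2 / k2.sum()


def _ssim_single(a: np.ndarray, b: np.ndarray, max_val: float) -> float:
    """SSIM of one 2-D channel, mean over valid (fully interior) windows."""
    win, sigma = _SSIM_WIN, _SSIM_SIGMA
    if a.shape[0] < win or a.shape[1] < win:
        raise ValueError(f"image smaller than the {win}x{win} SSIM window")
    kern = _gaussian_kernel(win, sigma)
    from numpy.lib.stride_tricks import sliding_window_view

    wa = sliding_window_view(a, (win, win))
    wb = sliding_window_view(b, (win, win))
    mu_a = np.einsum("ijkl,kl->ij", wa, kern)
    mu_b = np.einsum("ijkl,kl->ij", wb, kern)
    ea2 = np.einsum("ijkl,kl->ij", wa * wa, kern)
    eb2 = np.einsum("ijkl,kl->ij", wb * wb, kern)
    eab = np.einsum("ijkl,kl->ij", wa * wb, kern)
    va = ea2 - mu_a ** 2
    vb = eb2 - mu_b ** 2
    cab = eab - mu_a * mu_b
    c1 = (_SSIM_K1 * max_val) ** 2
    c2 = (_SSIM_K2 * max_val) ** 2
    num = (2 * mu_a * mu_b + c1) * (2 * cab + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)
    return float((num / den).mean())


def ssim(a: np.ndarray, b: np.ndarray, max_val: float = 1.0) -> float:
    """Mean SSIM; RGB images average the per-channel values."""
    a, b = _check_pair(a, b)
    if a.ndim == 2:
        return _ssim_single(a, b, max_val)
    return float(np.mean([_ssim_single(a[..., c], b[..., c], max_val)
                          for c in range(a.shape[-1])]))


def _mask_bbox(mask: np.ndarray, pad: int, shape) -> tuple[slice, slice]:
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty mask for masked image quality")
    y0 = max(0, ys.min() - pad)
    y1 = min(shape[0], ys.max() + 1 + pad)
    x0 = max(0, xs.min() - pad)
    x1 = min(shape[1], xs.max() + 1 + pad)
    return slice(y0, y1), slice(x0, x1)


def image_quality(
    x_ori: np.ndarray, x_rec: np.ndarray, mask: np.ndarray | None = None
) -> ImageQuality:
    """MAE/PSNR/SSIM between two [0, 1] rasters.

    With a mask, MAE/PSNR are restricted to masked pixels and SSIM is
    evaluated on the mask's bounding box (grown to the SSIM window if
    needed), since SSIM is window-based and undefined on scattered pixels.
    """
    a, b = _check_pair(x_ori, x_rec)
    if mask is None:
        return ImageQuality(mae(a, b), psnr(a, b), ssim(a, b), region="full")
    m = np.asarray(mask).astype(bool)
    ys, xs = _mask_bbox(m, pad=_SSIM_WIN // 2, shape=a.shape[:2])
    # widen tiny boxes so at least one SSIM window fits
    while ys.stop - ys.start < _SSIM_WIN:
        ys = slice(max(0, ys.start - 1), min(a.shape[0], ys.stop + 1))
    while xs.stop - xs.start < _SSIM_WIN:
        xs = slice(max(0, xs.start - 1), min(a.shape[1], xs.stop + 1))
    return ImageQuality(
        mae(a, b, m), psnr(a, b, m), ssim(a[ys, xs], b[ys, xs]), region="masked"
    )
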