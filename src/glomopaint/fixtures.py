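"""Deterministic synthetic-histology generator.

Every stage of the pipeline is exercised on slides produced here, so no
image download is ever needed.  The fixtures imitate PAS-stained kidney
cortex only qualitatively: a textured pink background (tissue), a white
margin (glass), and elliptical "glomeruli" whose interior texture separates
the two classes — normal glomeruli get a high-variance dotted dark-purple
interior, sclerosed ones a smooth homogeneous dark fill.  The variance gap
is what lets a tiny segmenter overfit them in the training smoke tests; no
claim of visual realism is made.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .slide_prep import rasterize_polygon
from .types import NORMAL, SCLEROSED, AnnotatedSlide, Annotation, GlomCrop

__all__ = ["make_fixture_slide", "make_fixture_crops"]

MARGIN = 24  # white (non-tissue) border width, px
_N_VERTICES = 32

# qualitative PAS-like palette (RGB, uint8)
_BG_PINK = np.array([228, 178, 202], dtype=float)
_NORMAL_BASE = np.array([146, 106, 158], dtype=float)
_NORMAL_DOT = np.array([88, 48, 110], dtype=float)
_SCLEROSED_FILL = np.array([84, 64, 96], dtype=float)
_WHITE = 247.0


def _ellipse_polygon(cx, cy, a, b, theta) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, _N_VERTICES, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ct, st = np.cos(theta), np.sin(theta)
    return np.column_stack([cx + x * ct - y * st, cy + x * st + y * ct])


def _textured_background(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    img = np.empty((h, w, 3), dtype=float)
    noise = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=3.0)
    noise = noise / (np.abs(noise).max() + 1e-9)
    fine = rng.normal(0.0, 4.0, size=(h, w))
    for c in range(3):
        img[:, :, c] = _BG_PINK[c] + 14.0 * noise + fine
    return img


def make_fixture_slide(
    width: int,
    height: int,
    n_normal: int,
    n_sclerosed: int,
    seed: int = 0,
    radius_range: tuple[float, float] = (22.0, 46.0),
) -> AnnotatedSlide:
    """Generate a synthetic annotated ROI.

    Glomeruli are placed by rejection sampling without overlap; if placement
    fails the error names how many fitted.  Fully deterministic under seed.
    """
    if width < 256 or height < 256:
        raise ValueError("fixture slides must be at least 256x256")
    if n_normal < 0 or n_sclerosed < 0:
        raise ValueError("glomerulus counts must be >= 0")
    rng = np.random.default_rng(seed)
    img = _textured_background(height, width, rng)
    # white glass margin around the tissue
    img[:MARGIN] = img[-MARGIN:] = _WHITE
    img[:, :MARGIN] = img[:, -MARGIN:] = _WHITE

    labels = [NORMAL] * n_normal + [SCLEROSED] * n_sclerosed
    placed: list[tuple[float, float, float]] = []  # (cx, cy, rmax)
    annotations: list[Annotation] = []
    lo, hi = radius_range
    for i, label in enumerate(labels):
        for _attempt in range(200):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            theta = rng.uniform(0.0, np.pi)
            rmax = max(a, b)
            cx = rng.uniform(MARGIN + rmax + 2, width - MARGIN - rmax - 2)
            cy = rng.uniform(MARGIN + rmax + 2, height - MARGIN - rmax - 2)
            if all(
                np.hypot(cx - px, cy - py) > rmax + pr + 6 for px, py, pr in placed
            ):
                break
        else:
            raise ValueError(
                f"could not place glomerulus {i + 1}/{len(labels)} without "
                f"overlap; only {len(placed)} fit on a {width}x{height} slide"
            )
        placed.append((cx, cy, rmax))
        poly = _ellipse_polygon(cx, cy, a, b, theta)
        annotations.append(Annotation(poly, label))
        interior = rasterize_polygon(poly, (height, width)).astype(bool)
        if label == NORMAL:
            fill = np.tile(_NORMAL_BASE, (interior.sum(), 1))
            fill += rng.normal(0.0, 9.0, size=fill.shape)
            dots = rng.random(interior.sum()) < 0.22
            fill[dots] = _NORMAL_DOT + rng.normal(0.0, 6.0, size=(dots.sum(), 3))
        else:
            fill = np.tile(_SCLEROSED_FILL, (interior.sum(), 1))
            fill += rng.normal(0.0, 1.5, size=fill.shape)
        img[interior] = fill

    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return AnnotatedSlide(out, annotations)


def make_fixture_crops(
    n: int, size: int = 256, seed: int = 0,
    radius_range: tuple[float, float] = (28.0, 64.0),
) -> list[GlomCrop]:
    """Centred sclerosed-glomerulus crop/mask pairs for inpainting training."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    crops: list[GlomCrop] = []
    lo, hi = min(radius_range[0], size / 5), min(radius_range[1], size / 3.2)
    for _ in range(n):
        img = _textured_background(size, size, rng)
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        theta = rng.uniform(0.0, np.pi)
        cx = cy = (size - 1) / 2.0
        poly = _ellipse_polygon(cx, cy, a, b, theta)
        mask = rasterize_polygon(poly, (size, size))
        interior = mask.astype(bool)
        fill = np.tile(_SCLEROSED_FILL, (interior.sum(), 1))
        fill += rng.normal(0.0, 1.5, size=fill.shape)
        img[interior] = fill
        crops.append(
            GlomCrop(
                image=np.clip(np.rint(img), 0, 255).astype(np.uint8),
                mask=mask,
                centre=(cx, cy),
                radius=float(max(a, b)),
            )
        )
    return crops
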