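"""Test-phase synthesis: paint new sclerosed glomeruli into a ROI.

For each chosen position a 256x256 patch is cut from the ROI, a generated
mask blanks out the future glomerulus (``x_gap = x_ori * (1 - mask)``), the
inpainting generator fills the hole, and the composite
``x_rec*mask + x_ori*(1-mask)`` is pasted back.  Pixels outside every mask
are bitwise identical to the input, and each pasted mask contributes one
traced sclerosed outline to the ROI's annotations.
"""

from __future__ import annotations

import logging

import numpy as np
from shapely.geometry import Polygon, box
from skimage.color import rgb2hsv
from skimage.measure import find_contours, label as cc_label

from .inpaint_model import InpaintGenerator
from .nd import Tensor
from .types import SCLEROSED, AnnotatedSlide, Annotation, MaskArtifact

logger = logging.getLogger(__name__)

__all__ = ["propose_positions", "synthesize_roi", "emit_training_set"]

CROP = 256
SATURATION_THRESHOLD = 0.15


def propose_positions(
    roi: AnnotatedSlide,
    n: int,
    seed: int = 0,
    crop: int = CROP,
    saturation_threshold: float = SATURATION_THRESHOLD,
    max_attempts_per_position: int = 200,
) -> list[tuple[int, int]]:
    """Choose up to ``n`` crop origins lying in tissue.

    A candidate crop must have mean HSV saturation above the threshold
    (tissue, not glass), must not intersect any existing glomerulus
    outline, and must not overlap an already accepted crop.  This
    operationalises "place where a pathologist would expect a glomerulus"
    as a reproducible heuristic.  Fewer than ``n`` hits returns the found
    subset with a warning.
    """
    if roi.height < crop or roi.width < crop:
        raise ValueError(f"roi smaller than a {crop}x{crop} crop")
    if n == 0:
        return []
    sat = rgb2hsv(roi.image)[:, :, 1]
    glom_boxes = []
    for ann in roi.annotations:
        p = Polygon(ann.polygon)
        if not p.is_valid:
            p = p.buffer(0)
        glom_boxes.append(p)
    rng = np.random.default_rng(seed)
    found: list[tuple[int, int]] = []
    for _ in range(n * max_attempts_per_position):
        if len(found) >= n:
            break
        x = int(rng.integers(0, roi.width - crop + 1))
        y = int(rng.integers(0, roi.height - crop + 1))
        window = box(x, y, x + crop, y + crop)
        if sat[y : y + crop, x : x + crop].mean() < saturation_threshold:
            continue
        if any(window.intersects(g) for g in glom_boxes):
            continue
        if any(
            abs(x - fx) < crop and abs(y - fy) < crop for fx, fy in found
        ):
            continue
        found.append((x, y))
    if len(found) < n:
        logger.warning("only %d of %d requested positions found", len(found), n)
    return found


def _trace_outline(mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray | None:
    """Trace the largest component's boundary as an (x, y) vertex list."""
    labels, nlab = cc_label(mask, connectivity=2, return_num=True)
    if nlab == 0:
        return None
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    keep = labels == int(np.argmax(areas))
    contours = find_contours(keep.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    # (row, col) -> (x, y), shifted into slide coordinates
    xy = np.column_stack([contour[:, 1] + offset[0], contour[:, 0] + offset[1]])
    step = max(1, len(xy) // 64)  # keep outlines compact
    return xy[::step]


def synthesize_roi(
    roi: AnnotatedSlide,
    masks: list[MaskArtifact],
    generator: InpaintGenerator,
    positions: list[tuple[int, int]],
    seed: int = 0,
) -> AnnotatedSlide:
    """Inpaint one generated glomerulus at each position and paste back.

    Masks are assigned to positions by a seeded random permutation.  The
    composite keeps hard mask edges; background pixels are untouched.
    """
    if len(masks) < len(positions):
        raise ValueError(
            f"need >= {len(positions)} masks, got {len(masks)}"
        )
    crop = generator.config.image_size
    for x, y in positions:
        if not (0 <= x <= roi.width - crop and 0 <= y <= roi.height - crop):
            raise ValueError(f"position ({x}, {y}) out of bounds")
    out_img = roi.image.copy()
    out_anns = list(roi.annotations)
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(len(masks))[: len(positions)]
    generator.eval()
    for (x, y), mi in zip(positions, assignment):
        gmask = masks[mi].raster.astype(np.float32)
        if gmask.shape != (crop, crop):
            raise ValueError(
                f"mask shape {gmask.shape} does not match crop {crop}"
            )
        x_ori = out_img[y : y + crop, x : x + crop].astype(np.float32) / 255.0
        x_ori_n = (2.0 * x_ori.transpose(2, 0, 1) - 1.0) * (1.0 - gmask)
        x_in = np.concatenate([x_ori_n, gmask[None]], axis=0)[None]
        x_rec = (generator(Tensor(x_in)).data[0] + 1.0) * 0.5
        rec8 = np.clip(np.rint(x_rec.transpose(1, 2, 0) * 255.0), 0, 255).astype(np.uint8)
        sel = gmask.astype(bool)
        patch = out_img[y : y + crop, x : x + crop]
        patch[sel] = rec8[sel]
        outline = _trace_outline(masks[mi].raster, (x, y))
        if outline is not None:
            out_anns.append(Annotation(outline, SCLEROSED))
    generator.train()
    return AnnotatedSlide(out_img, out_anns)


def emit_training_set(
    original: list, synthesized: list, fraction: float, seed: int = 0
) -> list:
    """Mix all original tiles with round(fraction * pool) synthesized tiles."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n_syn = int(round(fraction * len(synthesized)))
    if n_syn > len(synthesized):
        raise ValueError(
            f"synthesized pool too small: need {n_syn}, have {len(synthesized)}"
        )
    rng = np.random.default_rng(seed)
    chosen = [synthesized[i] for i in rng.permutation(len(synthesized))[:n_syn]]
    manifest = list(original) + chosen
    order = rng.permutation(len(manifest))
    return [manifest[i] for i in order]
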