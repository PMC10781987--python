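"""Slide preparation: downsampling, mask rasterization, overlap tiling and
centred glomerulus crops.

The preprocessing mirrors common whole-slide practice: slides are
downsampled (default 2x), outlines are burned into per-class binary masks,
and the slide is cut into 1024x1024 windows with stride 512 so that every
glomerulus appears whole in at least one window.  Sclerosed glomeruli are
additionally exported as 256x256 crops centred on the minimum enclosing
circle of their outline, which is what the inpainting network trains on.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon
from skimage.transform import downscale_local_mean

from . import io
from .types import NORMAL, SCLEROSED, AnnotatedSlide, Annotation, GlomCrop, Tile

logger = logging.getLogger(__name__)

DEFAULT_DOWNSAMPLE = 2
DEFAULT_WINDOW = 1024
DEFAULT_STRIDE = 512
DEFAULT_CROP = 256

__all__ = [
    "downsample_slide",
    "rasterize_annotations",
    "rasterize_polygon",
    "tile_with_overlap",
    "extract_glom_crop",
    "min_enclosing_circle",
    "prep_slide",
]


def downsample_slide(slide: AnnotatedSlide, factor: int) -> AnnotatedSlide:
    """Downsample raster and outlines by an integer factor (area mean).

    Trailing rows/columns that do not fill a complete ``factor x factor``
    block are dropped so every output pixel averages a full block.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    if slide.image.size == 0:
        raise ValueError("empty slide image")
    if factor > min(slide.height, slide.width):
        raise ValueError("downsample factor larger than the slide")
    if factor == 1:
        return AnnotatedSlide(slide.image, list(slide.annotations))
    h = (slide.height // factor) * factor
    w = (slide.width // factor) * factor
    img = slide.image[:h, :w].astype(np.float64)
    out = downscale_local_mean(img, (factor, factor, 1))
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    anns = [Annotation(a.polygon / factor, a.label) for a in slide.annotations]
    return AnnotatedSlide(out, anns)


def _valid_polygon(vertices: np.ndarray) -> Polygon | None:
    distinct = np.unique(np.round(vertices, 9), axis=0)
    if len(distinct) < 3:
        return None
    poly = Polygon(vertices)
    if poly.is_empty or poly.area == 0:
        return None
    return poly


def rasterize_polygon(
    vertices: np.ndarray, shape: tuple[int, int], offset: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Burn one polygon into a binary raster.

    A pixel (x, y) is foreground when its centre lies in the polygon's
    interior or on its boundary (point-in-polygon on pixel centres).
    ``offset`` shifts the polygon by (-ox, -oy) before rasterizing.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    verts = np.asarray(vertices, dtype=float) - np.asarray(offset, dtype=float)
    poly = _valid_polygon(verts)
    if poly is None:
        logger.warning("skipping degenerate polygon (<3 distinct vertices)")
        return mask
    if not poly.is_valid:
        # even-odd interpretation of a self-touching outline
        poly = poly.buffer(0)
    x0, y0, x1, y1 = poly.bounds
    xa = np.arange(max(0, int(np.floor(x0))), min(w, int(np.ceil(x1)) + 1))
    ya = np.arange(max(0, int(np.floor(y0))), min(h, int(np.ceil(y1)) + 1))
    if len(xa) == 0 or len(ya) == 0:
        return mask
    xx, yy = np.meshgrid(xa, ya)
    hit = shapely.intersects_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    mask[ya[0] : ya[-1] + 1, xa[0] : xa[-1] + 1] |= hit.astype(np.uint8)
    return mask


def rasterize_annotations(slide: AnnotatedSlide) -> tuple[np.ndarray, np.ndarray]:
    """Per-class binary masks (normal, sclerosed); same-class polygons union.

    A pixel claimed by both classes is assigned to sclerosed (and logged) —
    sclerosis is the minority class the pipeline exists to protect.
    """
    shape = (slide.height, slide.width)
    mask_n = np.zeros(shape, dtype=np.uint8)
    mask_s = np.zeros(shape, dtype=np.uint8)
    for ann in slide.annotations:
        m = rasterize_polygon(ann.polygon, shape)
        if ann.label == NORMAL:
            mask_n |= m
        else:
            mask_s |= m
    overlap = mask_n & mask_s
    if overlap.any():
        logger.warning(
            "%d pixels claimed by both classes; assigned to sclerosed",
            int(overlap.sum()),
        )
        mask_n &= ~overlap
    return mask_n, mask_s


def _axis_starts(dim: int, window: int, stride: int) -> list[int]:
    starts = list(range(0, dim - window + 1, stride))
    if not starts:
        starts = [0]
    if starts[-1] + window < dim:
        starts.append(dim - window)  # final window flush with the edge
    return starts


def tile_with_overlap(
    slide: AnnotatedSlide,
    masks: tuple[np.ndarray, np.ndarray] | None = None,
    window: int = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
) -> list[Tile]:
    """Cut the slide into overlapping ``window``-sized tiles.

    Origins advance by ``stride``; a partial final window is shifted flush
    to the image edge.  An image smaller than the window is reflect-padded
    to the window size and yields a single tile.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    img = slide.image
    if masks is None:
        mask_n, mask_s = rasterize_annotations(slide)
    else:
        mask_n, mask_s = masks
    h, w = img.shape[:2]
    if h < window or w < window:
        ph, pw = max(0, window - h), max(0, window - w)
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="reflect")
        mask_n = np.pad(mask_n, ((0, ph), (0, pw)), mode="reflect")
        mask_s = np.pad(mask_s, ((0, ph), (0, pw)), mode="reflect")
        return [Tile(img[:window, :window], mask_n[:window, :window],
                     mask_s[:window, :window], (0, 0))]
    tiles = []
    for y in _axis_starts(h, window, stride):
        for x in _axis_starts(w, window, stride):
            tiles.append(
                Tile(
                    img[y : y + window, x : x + window],
                    mask_n[y : y + window, x : x + window],
                    mask_s[y : y + window, x : x + window],
                    (x, y),
                )
            )
    return tiles


def min_enclosing_circle(vertices: np.ndarray) -> tuple[tuple[float, float], float]:
    """Centre and radius of the minimum enclosing circle of a point set."""
    arr = np.asarray(vertices, dtype=float)
    pts = MultiPoint(arr)
    radius = float(shapely.minimum_bounding_radius(pts))
    if radius == 0.0:  # all vertices coincide
        return (float(arr[0, 0]), float(arr[0, 1])), 0.0
    c = shapely.minimum_bounding_circle(pts).centroid
    return (float(c.x), float(c.y)), radius


def extract_glom_crop(
    slide: AnnotatedSlide, annotation: Annotation, crop: int = DEFAULT_CROP
) -> GlomCrop:
    """Crop ``crop x crop`` pixels centred on the glomerulus.

    The centre is the minimum-enclosing-circle centre of the outline.  Crops
    that would leave the slide are translated inward (never padded) so the
    crop contains only real tissue; the glomerulus may then sit off-centre.
    Glomeruli wider than the crop are flagged ``truncated`` but still emitted.
    """
    if slide.height < crop or slide.width < crop:
        raise ValueError(f"slide smaller than the {crop}x{crop} crop")
    (cx, cy), radius = min_enclosing_circle(annotation.polygon)
    x0 = int(round(cx)) - crop // 2
    y0 = int(round(cy)) - crop // 2
    x0 = min(max(x0, 0), slide.width - crop)
    y0 = min(max(y0, 0), slide.height - crop)
    image = slide.image[y0 : y0 + crop, x0 : x0 + crop]
    mask = rasterize_polygon(annotation.polygon, (crop, crop), offset=(x0, y0))
    return GlomCrop(
        image=image,
        mask=mask,
        centre=(cx, cy),
        radius=radius,
        truncated=bool(2 * radius > crop),
    )


def prep_slide(
    slide: AnnotatedSlide,
    out_dir,
    downsample: int = DEFAULT_DOWNSAMPLE,
    window: int = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
    crop: int = DEFAULT_CROP,
    prefix: str = "tile",
) -> dict:
    """Full preprocessing of one slide to disk: tiles, masks, crops, manifest."""
    out_dir = Path(out_dir)
    ds = downsample_slide(slide.clipped(), downsample)
    tiles = tile_with_overlap(ds, window=window, stride=stride)
    rows = []
    for i, t in enumerate(tiles):
        img_p = out_dir / "tiles" / f"{prefix}_{i:04d}.png"
        mn_p = out_dir / "masks" / f"{prefix}_{i:04d}_normal.png"
        ms_p = out_dir / "masks" / f"{prefix}_{i:04d}_sclerosed.png"
        io.write_image(img_p, t.image)
        io.write_mask(mn_p, t.mask_normal)
        io.write_mask(ms_p, t.mask_sclerosed)
        rows.append(
            {
                "tile": str(img_p),
                "mask_normal": str(mn_p),
                "mask_sclerosed": str(ms_p),
                "origin_x": t.origin[0],
                "origin_y": t.origin[1],
            }
        )
    io.write_manifest(
        out_dir / "manifest.tsv",
        rows,
        ["tile", "mask_normal", "mask_sclerosed", "origin_x", "origin_y"],
    )
    n_crops = 0
    for ann in ds.annotations:
        if ann.label != SCLEROSED:
            continue
        gc = extract_glom_crop(ds, ann, crop=crop)
        io.write_image(out_dir / "crops" / f"{prefix}_glom_{n_crops:04d}.png", gc.image)
        io.write_mask(out_dir / "crops" / f"{prefix}_glom_{n_crops:04d}_mask.png", gc.mask)
        n_crops += 1
    return {"n_tiles": len(tiles), "n_crops": n_crops, "out_dir": str(out_dir)}
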