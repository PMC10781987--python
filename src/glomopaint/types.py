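"""Core value types shared across the pipeline.

Conventions: rasters are numpy arrays with origin at the top-left, x
rightward and y downward; images are uint8 RGB (H, W, 3); masks are uint8
{0, 1} unless stated otherwise; boxes are 0-based half-open pixel intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NORMAL = "normal"
SCLEROSED = "sclerosed"
CLASSES = (NORMAL, SCLEROSED)


@dataclass
class Annotation:
    """A glomerulus outline: ordered (x, y) vertices plus a class label."""

    polygon: np.ndarray  # (n, 2) float
    label: str

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float).reshape(-1, 2)
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")


@dataclass
class AnnotatedSlide:
    """An RGB slide/ROI raster with polygon outlines for each glomerulus."""

    image: np.ndarray  # (H, W, 3) uint8
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("slide image must be (H, W, 3)")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def clipped(self) -> "AnnotatedSlide":
        """Clip every vertex into [0, W)x[0, H)."""
        anns = [
            Annotation(
                np.column_stack(
                    [
                        np.clip(a.polygon[:, 0], 0, self.width - 1),
                        np.clip(a.polygon[:, 1], 0, self.height - 1),
                    ]
                ),
                a.label,
            )
            for a in self.annotations
        ]
        return AnnotatedSlide(self.image, anns)


@dataclass
class Tile:
    """One overlapping window of a slide with its per-class masks."""

    image: np.ndarray  # (w, w, 3) uint8
    mask_normal: np.ndarray  # (w, w) uint8 {0,1}
    mask_sclerosed: np.ndarray  # (w, w) uint8 {0,1}
    origin: tuple[int, int]  # (x, y) in the (downsampled) slide


@dataclass
class GlomCrop:
    """A square crop centred on one sclerosed glomerulus.

    ``centre``/``radius`` come from the minimum enclosing circle of the
    outline; ``truncated`` flags glomeruli whose circle exceeds the crop.
    """

    image: np.ndarray  # (c, c, 3) uint8 — X_ori
    mask: np.ndarray  # (c, c) uint8 {0,1} — X_mask
    centre: tuple[float, float]
    radius: float
    truncated: bool = False


@dataclass
class MaskArtifact:
    """A binary glomerulus-shaped mask with provenance tracking."""

    raster: np.ndarray  # (s, s) uint8 {0,1}
    provenance: str = "real"  # real | sampled | postprocessed | scaled
    scale_factor: float = 1.0

    def __post_init__(self):
        self.raster = np.asarray(self.raster).astype(np.uint8)
        vals = np.unique(self.raster)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask raster must be binary {0,1}")

    @property
    def area(self) -> int:
        return int(self.raster.sum())


@dataclass
class InpaintSample:
    """The tensors flowing through one inpainting step, all in [0, 1]."""

    x_ori: np.ndarray  # (H, W, 3) float
    x_mask: np.ndarray  # (H, W) float {0,1}
    x_gap: np.ndarray  # (H, W, 3) float — x_ori * (1 - mask)
    x_input: np.ndarray  # (H, W, 4) float — concat(x_gap, mask)
    x_rec: np.ndarray | None = None  # generator output mapped to [0,1]


@dataclass
class LossReport:
    """All inpainting loss components and their weighted total for one batch."""

    adv_g: float = 0.0
    adv_l: float = 0.0
    l1_g: float = 0.0
    l1_l: float = 0.0
    perceptual: float = 0.0
    style: float = 0.0
    total: float = 0.0
    per_layer_perceptual: list[float] = field(default_factory=list)
    per_layer_style: list[float] = field(default_factory=list)
    disc_g: float = 0.0  # global discriminator objective
    disc_l: float = 0.0  # local discriminator objective

    def as_dict(self) -> dict:
        return {
            "adv_g": self.adv_g,
            "adv_l": self.adv_l,
            "l1_g": self.l1_g,
            "l1_l": self.l1_l,
            "perceptual": self.perceptual,
            "style": self.style,
            "total": self.total,
            "disc_g": self.disc_g,
            "disc_l": self.disc_l,
        }


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    dice: float


@dataclass
class ImageQuality:
    mae: float
    psnr: float  # dB; +inf when images are identical
    ssim: float
    region: str = "full"  # full | masked


@dataclass
class MetricsReport:
    per_class: dict[str, ClassMetrics] = field(default_factory=dict)
    image_quality: dict[str, ImageQuality] = field(default_factory=dict)
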