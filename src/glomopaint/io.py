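"""Reading and writing the on-disk formats: PNG rasters, GeoJSON outlines,
TSV manifests."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from PIL import Image

from .types import CLASSES, AnnotatedSlide, Annotation

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_annotations",
    "write_annotations",
    "read_slide",
    "write_manifest",
    "read_manifest",
]


def read_image(path) -> np.ndarray:
    """Load an 8-bit RGB PNG as (H, W, 3) uint8."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path, image: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_mask(path) -> np.ndarray:
    """Load a 0/255 PNG mask as {0,1} uint8."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


def read_annotations(path) -> list[Annotation]:
    """Parse a GeoJSON FeatureCollection with a ``classification`` property.

    The classification may be a bare string or an object with a ``name``
    field (as exported by common annotation tools).
    """
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError("annotations must be a GeoJSON FeatureCollection")
    out: list[Annotation] = []
    for feat in data.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError(f"unsupported geometry type {geom.get('type')!r}")
        cls = feat.get("properties", {}).get("classification")
        if isinstance(cls, dict):
            cls = cls.get("name")
        if cls not in CLASSES:
            raise ValueError(f"classification must be one of {CLASSES}, got {cls!r}")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        # GeoJSON rings repeat the first vertex at the end
        if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        out.append(Annotation(ring, cls))
    return out


def write_annotations(path, annotations: list[Annotation]) -> None:
    feats = []
    for ann in annotations:
        ring = ann.polygon.tolist()
        ring.append(ring[0])
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"classification": ann.label},
            }
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_slide(image_path, annotations_path=None) -> AnnotatedSlide:
    anns = read_annotations(annotations_path) if annotations_path else []
    return AnnotatedSlide(read_image(image_path), anns)


def write_manifest(path, rows: list[dict], fields: list[str]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_manifest(path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
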