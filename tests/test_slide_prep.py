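"""Slide preparation: downsampling, rasterization, tiling, glomerulus crops."""

import itertools

import numpy as np
import pytest

from glomopaint.slide_prep import (
    downsample_slide,
    extract_glom_crop,
    min_enclosing_circle,
    rasterize_annotations,
    rasterize_polygon,
    tile_with_overlap,
)
from glomopaint.types import AnnotatedSlide, Annotation


def _slide(h, w, anns=()):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    return AnnotatedSlide(img, list(anns))


def _point_in_polygon_scan(vertices, shape):
    """Brute-force oracle: even-odd ray casting incl. boundary on pixel centres."""
    from shapely import intersects_xy
    from shapely.geometry import Polygon

    poly = Polygon(vertices)
    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            if intersects_xy(poly, x, y):
                mask[y, x] = 1
    return mask


def _brute_force_mec(points):
    """Minimum enclosing circle by enumerating pairs and triples."""
    pts = np.asarray(points, dtype=float)

    def circle_two(a, b):
        c = (a + b) / 2
        return c, np.linalg.norm(a - b) / 2

    def circle_three(a, b, c):
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            return None
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
        centre = np.array([ux, uy])
        return centre, np.linalg.norm(a - centre)

    best = None
    candidates = []
    for a, b in itertools.combinations(pts, 2):
        candidates.append(circle_two(a, b))
    for a, b, c in itertools.combinations(pts, 3):
        circ = circle_three(a, b, c)
        if circ is not None:
            candidates.append(circ)
    for centre, r in candidates:
        if np.all(np.linalg.norm(pts - centre, axis=1) <= r + 1e-9):
            if best is None or r < best[1]:
                best = (centre, r)
    return best


class TestDownsample:
    def test_identity_factor(self, fixture_slide):
        out = downsample_slide(fixture_slide, 1)
        assert np.array_equal(out.image, fixture_slide.image)
        for a, b in zip(out.annotations, fixture_slide.annotations):
            assert np.array_equal(a.polygon, b.polygon)

    def test_coordinates_and_shape_halved(self):
        slide = _slide(2048, 2048, [Annotation([(300, 300), (400, 300), (400, 400)], "normal")])
        out = downsample_slide(slide, 2)
        assert out.image.shape == (1024, 1024, 3)
        assert np.allclose(out.annotations[0].polygon[0], (150, 150))

    def test_area_mean(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[0, 0] = 255  # one bright pixel in a 2x2 block
        out = downsample_slide(AnnotatedSlide(img, []), 2)
        assert out.image[0, 0, 0] == round(255 / 4)

    def test_invalid_factor(self, fixture_slide):
        with pytest.raises(ValueError):
            downsample_slide(fixture_slide, 0)
        with pytest.raises(ValueError):
            downsample_slide(_slide(16, 16), 32)


class TestRasterize:
    def test_no_annotations_all_zero(self):
        mn, ms = rasterize_annotations(_slide(32, 32))
        assert mn.sum() == 0 and ms.sum() == 0

    def test_square_matches_point_scan_oracle(self):
        square = [(10, 10), (20, 10), (20, 20), (10, 20)]
        slide = _slide(32, 32, [Annotation(square, "sclerosed")])
        mn, ms = rasterize_annotations(slide)
        oracle = _point_in_polygon_scan(square, (32, 32))
        assert np.array_equal(ms, oracle)
        assert ms.sum() == 11 * 11  # boundary included
        assert mn.sum() == 0

    def test_triangle_matches_point_scan_oracle(self):
        tri = [(3.2, 4.1), (27.5, 8.3), (12.0, 26.7)]
        slide = _slide(32, 32, [Annotation(tri, "normal")])
        mn, _ms = rasterize_annotations(slide)
        assert np.array_equal(mn, _point_in_polygon_scan(tri, (32, 32)))

    def test_disjoint_classes_disjoint_masks(self):
        a = Annotation([(2, 2), (10, 2), (10, 10), (2, 10)], "normal")
        b = Annotation([(20, 20), (28, 20), (28, 28), (20, 28)], "sclerosed")
        mn, ms = rasterize_annotations(_slide(32, 32, [a, b]))
        assert mn.sum() > 0 and ms.sum() > 0
        assert not np.any(mn & ms)

    def test_overlap_assigned_to_sclerosed(self, caplog):
        a = Annotation([(2, 2), (12, 2), (12, 12), (2, 12)], "normal")
        b = Annotation([(8, 8), (18, 8), (18, 18), (8, 18)], "sclerosed")
        mn, ms = rasterize_annotations(_slide(32, 32, [a, b]))
        assert not np.any(mn & ms)
        assert ms[10, 10] == 1 and mn[10, 10] == 0

    def test_degenerate_polygon_skipped(self):
        m = rasterize_polygon(np.array([(5, 5), (5, 5), (5, 5)]), (16, 16))
        assert m.sum() == 0

    def test_rasterize_bbox_roundtrip_on_rectangles(self):
        rect = [(4, 6), (25, 6), (25, 17), (4, 17)]
        m = rasterize_polygon(np.array(rect, dtype=float), (32, 32))
        ys, xs = np.nonzero(m)
        assert (xs.min(), ys.min(), xs.max(), ys.max()) == (4, 6, 25, 17)


class TestTiling:
    def test_single_tile_exact_fit(self):
        tiles = tile_with_overlap(_slide(1024, 1024), window=1024, stride=512)
        assert len(tiles) == 1 and tiles[0].origin == (0, 0)

    def test_nine_tiles_2048(self):
        tiles = tile_with_overlap(_slide(2048, 2048), window=1024, stride=512)
        origins = {t.origin for t in tiles}
        assert len(tiles) == 9
        assert origins == {(x, y) for x in (0, 512, 1024) for y in (0, 512, 1024)}

    def test_two_tiles_1536_wide(self):
        tiles = tile_with_overlap(_slide(1024, 1536), window=1024, stride=512)
        assert [t.origin for t in tiles] == [(0, 0), (512, 0)]

    def test_flush_shift_on_non_multiple(self):
        tiles = tile_with_overlap(_slide(1024, 1300), window=1024, stride=512)
        assert [t.origin for t in tiles] == [(0, 0), (276, 0)]

    def test_small_image_reflect_padded(self):
        tiles = tile_with_overlap(_slide(100, 80), window=128, stride=64)
        assert len(tiles) == 1
        assert tiles[0].image.shape == (128, 128, 3)

    @pytest.mark.parametrize("h,w", [(1024, 1024), (1500, 2048), (1025, 1024)])
    def test_full_coverage(self, h, w):
        tiles = tile_with_overlap(_slide(h, w), window=1024, stride=512)
        cover = np.zeros((h, w), dtype=bool)
        for t in tiles:
            x, y = t.origin
            cover[y : y + 1024, x : x + 1024] = True
        assert cover.all()


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    st.integers(64, 300), st.integers(64, 300),
    st.integers(32, 64), st.integers(8, 32),
)
def test_tiling_coverage_property(h, w, window, stride):
    """Every pixel is covered by at least one tile whenever stride <= window."""
    tiles = tile_with_overlap(_slide(h, w), window=window, stride=stride)
    cover = np.zeros((max(h, window), max(w, window)), dtype=bool)
    for t in tiles:
        x, y = t.origin
        assert t.image.shape == (window, window, 3)
        cover[y : y + window, x : x + window] = True
    assert cover[:h, :w].all()


class TestMinEnclosingCircle:
    def test_square(self):
        square = [(250, 250), (350, 250), (350, 350), (250, 350)]
        (cx, cy), r = min_enclosing_circle(np.array(square))
        assert np.allclose((cx, cy), (300, 300), atol=1e-6)
        assert np.isclose(r, 50 * np.sqrt(2), rtol=1e-6)

    def test_equilateral_triangle_circumcircle(self):
        s = 60.0
        tri = np.array([(0, 0), (s, 0), (s / 2, s * np.sqrt(3) / 2)]) + 100
        (cx, cy), r = min_enclosing_circle(tri)
        assert np.isclose(r, s / np.sqrt(3), rtol=1e-6)  # circumradius
        assert np.allclose((cx, cy), tri.mean(axis=0), atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(7, 2))
        (cx, cy), r = min_enclosing_circle(pts)
        centre_o, r_o = _brute_force_mec(pts)
        assert np.isclose(r, r_o, rtol=1e-6)
        assert np.allclose((cx, cy), centre_o, atol=1e-5)


class TestGlomCrop:
    def test_square_polygon_crop_box(self):
        square = [(250, 250), (350, 250), (350, 350), (250, 350)]
        slide = _slide(600, 600, [Annotation(square, "sclerosed")])
        crop = extract_glom_crop(slide, slide.annotations[0], crop=256)
        assert np.allclose(crop.centre, (300.0, 300.0))
        assert crop.image.shape == (256, 256, 3)
        # mask lands where the square maps inside the [172, 428) crop box
        ys, xs = np.nonzero(crop.mask)
        assert xs.min() == 250 - 172 and xs.max() == 350 - 172

    def test_degenerate_point_cluster_clamped(self):
        pts = [(100, 100)] * 4
        slide = _slide(400, 400, [Annotation(pts, "sclerosed")])
        crop = extract_glom_crop(slide, slide.annotations[0], crop=256)
        assert crop.radius == 0.0
        assert crop.centre == (100.0, 100.0)
        assert crop.image.shape == (256, 256, 3)  # translated inward, not padded

    def test_truncation_flag(self):
        big = [(10, 10), (500, 10), (500, 500), (10, 500)]
        slide = _slide(600, 600, [Annotation(big, "sclerosed")])
        crop = extract_glom_crop(slide, slide.annotations[0], crop=256)
        assert crop.truncated

    def test_mask_centred_when_unclamped(self, fixture_slide):
        for ann in fixture_slide.annotations:
            if ann.label != "sclerosed":
                continue
            crop = extract_glom_crop(fixture_slide, ann, crop=256)
            if crop.truncated:
                continue
            ys, xs = np.nonzero(crop.mask)
            if len(ys) == 0:
                continue
            (cx, cy), r = crop.centre, crop.radius
            # centroid near the crop centre unless clamping moved the box
            cx0 = min(max(round(cx) - 128, 0), fixture_slide.width - 256)
            cy0 = min(max(round(cy) - 128, 0), fixture_slide.height - 256)
            assert abs(xs.mean() - (cx - cx0)) <= r
            assert abs(ys.mean() - (cy - cy0)) <= r
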