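"""The seven lesion features against analytic shapes and independent oracles."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk, ellipse, polygon

from lesiongraph import features as F
from lesiongraph import synthetic as S
from lesiongraph.dataset_io import UltrasoundSample, apply_mask


def circle_mask(radius=50, size=160):
    m = np.zeros((size, size), bool)
    rr, cc = disk((size // 2, size // 2), radius)
    m[rr, cc] = True
    return m


def star_mask(amp=0.3, n=10, radius=50, size=220):
    th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r = radius * (1 + amp * np.cos(n * th))
    rows = size / 2 + r * np.sin(th)
    cols = size / 2 + r * np.cos(th)
    m = np.zeros((size, size), bool)
    rr, cc = polygon(rows, cols, m.shape)
    m[rr, cc] = True
    return m


# -- contour extraction ------------------------------------------------------

def test_contour_of_largest_component():
    m = np.zeros((120, 120), bool)
    m[10:35, 10:30] = True  # 500 px
    m[80:90, 80:85] = True  # 50 px
    c = F.extract_contour(m)
    # contour vertices must lie inside the big component's bounding box
    assert c[:, 0].max() < 40 and c[:, 1].max() < 40
    assert abs(F.polygon_area(c) - 500) / 500 < 0.05


def test_contour_errors():
    with pytest.raises(ValueError, match="empty"):
        F.extract_contour(np.zeros((10, 10), bool))
    tiny = np.zeros((10, 10), bool)
    tiny[5, 5] = True
    with pytest.raises(ValueError, match="degenerate"):
        F.extract_contour(tiny)


def test_rectangle_contour_area_and_whr():
    m = np.zeros((100, 100), bool)
    m[40:60, 30:70] = True  # 20 rows x 40 cols
    c = F.extract_contour(m)
    assert abs(F.polygon_area(c) - 800) / 800 < 0.02
    assert F.width_height_ratio(c) == pytest.approx(2.0, abs=0.05)


# -- polygon geometry --------------------------------------------------------

def test_polygon_area_closed_forms():
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
    assert F.polygon_area(square) == pytest.approx(1.0)
    tri = np.array([[0, 0], [4, 0], [0, 3]], float)
    assert F.polygon_area(tri) == pytest.approx(6.0)
    with pytest.raises(ValueError):
        F.polygon_area(np.array([[0, 0], [1, 1]], float))


def test_polygon_perimeter_closed_forms():
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
    assert F.polygon_perimeter(square) == pytest.approx(4.0)
    tri = np.array([[0, 0], [3, 0], [3, 4]], float)  # 3-4-5
    assert F.polygon_perimeter(tri) == pytest.approx(12.0)


def test_random_polygon_area_matches_shapely_oracle(rng):
    # independent geometry oracle on random simple (star-convex) 20-gons
    from shapely.geometry import Polygon as ShapelyPolygon

    for _ in range(20):
        th = np.sort(rng.uniform(0, 2 * np.pi, 20))
        r = rng.uniform(5, 30, 20)
        pts = np.column_stack([r * np.sin(th), r * np.cos(th)])
        sp = ShapelyPolygon(pts)
        assert F.polygon_area(pts) == pytest.approx(sp.area, rel=1e-12)
        assert F.polygon_perimeter(pts) == pytest.approx(sp.length, rel=1e-12)


@given(
    dr=st.floats(-50, 50),
    dc=st.floats(-50, 50),
    scale=st.floats(0.5, 3.0),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_polygon_geometry_similarity_transforms(dr, dc, scale):
    """Area scales with the square, perimeter with the factor, under similarity."""
    th = np.linspace(0, 2 * np.pi, 17, endpoint=False)
    base = np.column_stack([10 * np.sin(th), 14 * np.cos(th)])
    a0, p0 = F.polygon_area(base), F.polygon_perimeter(base)
    moved = base * scale + np.array([dr, dc])
    assert F.polygon_area(moved) == pytest.approx(a0 * scale**2, rel=1e-9)
    assert F.polygon_perimeter(moved) == pytest.approx(p0 * scale, rel=1e-9)


def test_rasterized_circle_perimeter():
    c = F.extract_contour(circle_mask(50))
    assert F.polygon_perimeter(c) == pytest.approx(2 * math.pi * 50, rel=0.03)


# -- solidity / circularity --------------------------------------------------

def test_convex_hull_ratio_convex_and_star(rng):
    from shapely.geometry import Polygon as ShapelyPolygon

    ell = np.zeros((160, 160), bool)
    rr, cc = ellipse(80, 80, 30, 50)
    ell[rr, cc] = True
    assert F.convex_hull_ratio(F.extract_contour(ell)) == pytest.approx(1.0, abs=0.02)

    c = F.extract_contour(star_mask())
    sp = ShapelyPolygon(c)
    oracle = sp.convex_hull.area / sp.area
    assert F.convex_hull_ratio(c) == pytest.approx(oracle, rel=1e-6)
    assert F.convex_hull_ratio(c) > 1.1

    # CHR >= 1 for arbitrary star-convex polygons
    for _ in range(10):
        th = np.sort(rng.uniform(0, 2 * np.pi, 30))
        pts = np.column_stack(
            [rng.uniform(10, 40, 30) * np.sin(th), rng.uniform(10, 40, 30) * np.cos(th)]
        )
        assert F.convex_hull_ratio(pts) >= 1.0 - 1e-9


def test_circularity_closed_forms():
    circ = F.ContourGeometry(area=math.pi * 50**2, perimeter=2 * math.pi * 50, hull_area=0)
    assert F.circularity(circ) == pytest.approx(0.0, abs=1e-12)
    square = F.ContourGeometry(area=25.0, perimeter=20.0, hull_area=25.0)
    assert F.circularity(square) == pytest.approx(1 - math.pi / 4, abs=1e-12)
    rect = F.ContourGeometry(area=10.0, perimeter=22.0, hull_area=10.0)  # 10x1
    assert F.circularity(rect) == pytest.approx(1 - 40 * math.pi / 484, abs=1e-12)
    with pytest.raises(ValueError):
        F.circularity(F.ContourGeometry(area=1.0, perimeter=0.0, hull_area=1.0))


def test_discrete_circle_circularity_near_zero():
    g = F.contour_geometry(F.extract_contour(circle_mask(50)))
    assert F.circularity(g) == pytest.approx(0.0, abs=0.03)


def test_circularity_monotone_in_spike_amplitude():
    # fixed base radius, growing spike amplitude -> growing Fcirc
    values = []
    for amp in (0.0, 0.1, 0.2, 0.3, 0.4):
        g = F.contour_geometry(F.extract_contour(star_mask(amp=amp)))
        values.append(F.circularity(g))
    assert all(b > a for a, b in zip(values, values[1:]))


def test_isoperimetric_bound_on_random_masks(rng):
    for seed in range(5):
        params = S.sample_params(int(seed % 2), np.random.default_rng(seed))
        g = F.contour_geometry(F.extract_contour(S.generate_lesion_mask(params)))
        assert 4 * math.pi * g.area <= g.perimeter**2 * 1.01


# -- enclosing ellipse -------------------------------------------------------

def test_enclosing_ellipse_self_recovery():
    m = np.zeros((160, 160), bool)
    rr, cc = ellipse(80, 80, 15, 30)
    m[rr, cc] = True
    c = F.extract_contour(m)
    fit = F.enclosing_ellipse(c)
    a, b = fit.semi_axes
    assert a == pytest.approx(30, rel=0.03)
    assert b == pytest.approx(15, rel=0.03)
    g = F.contour_geometry(c)
    assert F.ellipse_ratio(fit, g) == pytest.approx(1.0, abs=0.05)


def test_enclosing_ellipse_circle_area():
    c = F.extract_contour(circle_mask(40))
    fit = F.enclosing_ellipse(c)
    assert fit.area == pytest.approx(math.pi * 40**2, rel=0.03)


def test_enclosing_ellipse_contains_all_vertices():
    c = F.extract_contour(star_mask())
    fit = F.enclosing_ellipse(c)
    a, b = fit.semi_axes
    ctr = np.array(fit.center)
    u = np.array([math.cos(fit.angle), math.sin(fit.angle)])
    # rotate vertices into the ellipse frame
    d = c - ctr
    x = d @ u
    y = d @ np.array([-u[1], u[0]])
    assert ((x / (a * 1.01)) ** 2 + (y / (b * 1.01)) ** 2 <= 1.0).all()


def test_enclosing_ellipse_plus_sign_matches_grid_oracle():
    # plus-sign polygon; oracle = best axis-aligned-by-symmetry ellipse on a grid
    pts = np.array(
        [
            [3, 1], [3, -1], [1, -1], [1, -3], [-1, -3], [-1, -1],
            [-3, -1], [-3, 1], [-1, 1], [-1, 3], [1, 3], [1, 1],
        ],
        float,
    )
    fit = F.enclosing_ellipse(pts)
    best = np.inf
    for a in np.linspace(2.0, 5.0, 301):
        for b in np.linspace(2.0, 5.0, 301):
            if ((pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 <= 1.0 + 1e-9).all():
                best = min(best, math.pi * a * b)
    assert fit.area == pytest.approx(best, rel=0.05)


def test_enclosing_ellipse_collinear_errors():
    pts = np.column_stack([np.arange(6, dtype=float), np.arange(6, dtype=float)])
    with pytest.raises(ValueError):
        F.enclosing_ellipse(pts)


# -- bounding box ------------------------------------------------------------

def test_width_height_ratio_shapes():
    sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
    assert F.width_height_ratio(sq) == pytest.approx(1.0)
    m = np.zeros((160, 160), bool)
    rr, cc = ellipse(80, 80, 15, 30)  # wider than tall
    m[rr, cc] = True
    assert F.width_height_ratio(F.extract_contour(m)) == pytest.approx(2.0, abs=0.05)


# -- keypoint counts ---------------------------------------------------------

def test_sift_uniform_image_and_determinism():
    img = np.full((128, 128), 90, np.uint8)
    mask = circle_mask(30, 128)
    assert F.sift_keypoint_count(img, mask) == 0
    params = S.SyntheticParams(label=1, n_spikes=12, spike_amplitude=0.3, seed=5)
    m = S.generate_lesion_mask(params)
    im = S.render_ultrasound_image(m, params)
    masked = np.where(m, im, 0).astype(np.uint8)
    c1 = F.sift_keypoint_count(masked, m)
    c2 = F.sift_keypoint_count(masked, m)
    assert c1 == c2 and c1 > 0


def test_sift_spiky_beats_smooth_at_equal_area():
    wins = 0
    n = 25
    for i in range(n):
        base = S.SyntheticParams(
            label=0, base_radius=45, wh_bias=1.0, n_spikes=12,
            spike_amplitude=0.0, margin_blur=0.5, seed=i,
        )
        spiky = replace(
            base, spike_amplitude=0.3, base_radius=45 / math.sqrt(1 + 0.3**2 / 2)
        )
        counts = []
        for p in (base, spiky):
            m = S.generate_lesion_mask(p)
            im = S.render_ultrasound_image(m, p)
            counts.append(F.sift_keypoint_count(np.where(m, im, 0).astype(np.uint8), m))
        wins += counts[1] > counts[0]
    assert wins >= 0.9 * n


def test_harris_uniform_and_square_corners():
    img = np.full((96, 96), 120, np.uint8)
    mask = np.zeros((96, 96), bool)
    mask[30:60, 30:60] = True
    assert F.harris_corner_count(img, mask) == 0
    sq = np.zeros((96, 96), np.uint8)
    sq[30:60, 30:60] = 200
    n = F.harris_corner_count(sq, mask)
    assert 3 <= n <= 5  # 4 +/- 1 corners


def test_harris_star_beats_ellipse():
    wins = 0
    n = 25
    for i in range(n):
        ell = S.SyntheticParams(
            label=0, base_radius=45, wh_bias=1.4, n_spikes=0,
            spike_amplitude=0.0, margin_blur=0.0, speckle=0.0, seed=i,
        )
        star = replace(
            ell, n_spikes=12, spike_amplitude=0.3,
            base_radius=45 / math.sqrt(1 + 0.3**2 / 2),
        )
        counts = []
        for p in (ell, star):
            m = S.generate_lesion_mask(p)
            im = S.render_ultrasound_image(m, p)
            counts.append(F.harris_corner_count(np.where(m, im, 0).astype(np.uint8), m))
        wins += counts[1] > counts[0]
    assert wins >= 0.9 * n


# -- margin brightness -------------------------------------------------------

def test_margin_brightness_constant_and_disk():
    img = np.full((128, 128), 100, np.uint8)
    mask = circle_mask(30, 128)
    assert F.margin_brightness(img, mask) == pytest.approx(100.0)
    sharp = np.where(mask, 200, 0).astype(np.uint8)
    val = F.margin_brightness(sharp, mask)
    # pixel-count oracle from the disk geometry: band mean = 200 * inner/(inner+outer)
    rr, cc = np.ogrid[:128, :128]
    dist = np.hypot(rr - 64, cc - 64)
    inner = (mask & (dist >= 30 - 10)).sum()
    outer = (~mask & (dist <= 30 + 10)).sum()
    expected = 200.0 * inner / (inner + outer)
    assert val == pytest.approx(expected, abs=3.0)
    assert 0 <= val <= 255
    with pytest.raises(ValueError):
        F.margin_brightness(img, np.ones_like(mask))


# -- composition -------------------------------------------------------------

def test_extract_features_on_synthetic_batches(synth_dataset):
    _samples, table = synth_dataset
    ben = table[table.label == 0]
    mal = table[table.label == 1]
    assert ben.solidity.mean() <= 1.05
    assert (ben.wh_ratio > 1).mean() > 0.95
    assert ben.circularity.mean() < 0.15
    assert mal.solidity.mean() > 1.1
    assert mal.circularity.mean() > 0.3
    arr = table[F.FEATURE_NAMES].to_numpy(float)
    assert np.isfinite(arr).all()


def test_features_invariant_to_translation_and_intensity():
    params = S.SyntheticParams(label=1, n_spikes=10, spike_amplitude=0.25, seed=9)
    mask = S.generate_lesion_mask(params)
    image = S.render_ultrasound_image(mask, params)
    sample = UltrasoundSample("orig", image, mask, 1)
    shifted = UltrasoundSample(
        "shifted", np.roll(image, (7, -11), (0, 1)), np.roll(mask, (7, -11), (0, 1)), 1
    )
    f0, f1 = F.extract_features(sample), F.extract_features(shifted)
    assert np.allclose(f0.as_array(), f1.as_array(), rtol=1e-6)
    # geometric features ignore a uniform intensity shift
    brighter = UltrasoundSample(
        "bright", np.clip(image.astype(int) + 40, 0, 255).astype(np.uint8), mask, 1
    )
    f2 = F.extract_features(brighter)
    for name in ("solidity", "wh_ratio", "ellipse_ratio", "circularity"):
        assert getattr(f0, name) == pytest.approx(getattr(f2, name), rel=1e-9)


def test_extraction_error_names_sample():
    bad = UltrasoundSample.__new__(UltrasoundSample)
    bad.id = "broken"
    bad.image = np.zeros((32, 32), np.uint8)
    bad.mask = np.zeros((32, 32), bool)
    bad.mask[5, 5] = True
    bad.label = 0
    with pytest.raises(ValueError, match="broken"):
        F.extract_features(bad)
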