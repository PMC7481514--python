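"""Shape-feature geometry: corner-point hull, rotating calipers, invariants.

The independent oracles live here: a gift-wrapping (Jarvis-march) convex
hull and an O(n^2) all-pairs diameter, both computed directly from the
pixel corner points.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk

from ryenue.errors import EmptyMaskError
from ryenue.imaging import (
    extract_features,
    pixel_corner_points,
    rotating_calipers_diameter,
)

from conftest import random_mask


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    """Jarvis-march convex hull (CCW in image coordinates); oracle only."""
    pts = [tuple(p) for p in np.unique(points, axis=0)]
    if len(pts) == 1:
        return np.asarray(pts)
    start = min(pts)  # lexicographically smallest is on the hull
    hull = []
    p = start
    while True:
        hull.append(p)
        q = pts[0] if pts[0] != p else pts[1]
        for r in pts:
            if r == p:
                continue
            cross = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
            if q == p or cross < 0 or (
                cross == 0
                and (r[0] - p[0]) ** 2 + (r[1] - p[1]) ** 2
                > (q[0] - p[0]) ** 2 + (q[1] - p[1]) ** 2
            ):
                q = r
        p = q
        if p == start:
            break
    return np.asarray(hull)


def shoelace_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_perimeter(vertices: np.ndarray) -> float:
    d = np.diff(np.vstack([vertices, vertices[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def brute_force_diameter(points: np.ndarray) -> float:
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


# ---------------------------------------------------------------------------
# exact cases
# ---------------------------------------------------------------------------

def test_filled_square_features_are_exact():
    """A filled 100x100 square is pixel-convex: compactness is exactly 1 and
    every other feature follows from the corner-point convention."""
    m = np.zeros((120, 120), bool)
    m[10:110, 10:110] = True
    f = extract_features(m)
    assert f.area == 10000
    assert f.convex_hull_area == pytest.approx(10000, abs=1e-9)
    assert f.compactness == pytest.approx(1.0, abs=1e-12)
    assert f.convex_hull_circumference == pytest.approx(400.0, abs=1e-9)
    assert f.caliper_length == pytest.approx(100 * math.sqrt(2), rel=1e-12)
    assert (f.width, f.height) == (100, 100)


def test_single_pixel_is_a_unit_square():
    m = np.zeros((5, 7), bool)
    m[2, 3] = True
    f = extract_features(m)
    assert f.area == 1
    assert f.convex_hull_area == pytest.approx(1.0)
    assert f.compactness == pytest.approx(1.0)
    assert f.caliper_length == pytest.approx(math.sqrt(2), rel=1e-12)
    assert (f.width, f.height) == (1, 1)


def test_empty_mask_raises():
    with pytest.raises(EmptyMaskError):
        extract_features(np.zeros((4, 4), bool))


def test_disk_caliper_and_compactness():
    """For a rasterised disk the hull diameter tracks 2r, and compactness
    approaches 1 from below as the corner-point hull's O(r) excess over the
    O(r^2) pixel area vanishes (>= 0.98 from r = 40 up)."""
    for r, c_min in [(30, 0.97), (40, 0.98), (60, 0.98)]:
        m = np.zeros((2 * r + 10, 2 * r + 10), bool)
        rr, cc = draw_disk((r + 5, r + 5), r)
        m[rr, cc] = True
        f = extract_features(m)
        assert 2 * r <= f.caliper_length <= 2 * r + 3
        assert c_min <= f.compactness < 1.0


# ---------------------------------------------------------------------------
# oracle equivalence on random masks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(60))
def test_hull_and_caliper_match_brute_force(seed):
    """Rotating calipers and the qhull-based hull agree exactly with the
    gift-wrapping + all-pairs oracles on random small masks."""
    rng = np.random.default_rng(seed)
    m = random_mask(rng)
    f = extract_features(m)
    corners = pixel_corner_points(m)
    oracle_hull = gift_wrap_hull(corners)
    assert f.convex_hull_area == pytest.approx(shoelace_area(oracle_hull), abs=1e-9)
    assert f.convex_hull_circumference == pytest.approx(
        polygon_perimeter(oracle_hull), abs=1e-9
    )
    assert f.caliper_length == pytest.approx(brute_force_diameter(corners), abs=1e-9)
    assert 0 < f.compactness <= 1.0 + 1e-12


def test_rotating_calipers_on_degenerate_polygons():
    assert rotating_calipers_diameter(np.array([[0.0, 0.0]])) == 0.0
    assert rotating_calipers_diameter(np.array([[0.0, 0.0], [3.0, 4.0]])) == 5.0


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(0, 10_000))
def test_adding_pixels_never_shrinks_extents(seed):
    rng = np.random.default_rng(seed)
    m = random_mask(rng)
    f1 = extract_features(m)
    grown = m.copy()
    free = np.argwhere(~grown)
    extra = free[rng.integers(0, len(free))]
    grown[extra[0], extra[1]] = True
    f2 = extract_features(grown)
    assert f2.area > f1.area
    assert f2.convex_hull_area >= f1.convex_hull_area - 1e-9
    assert f2.caliper_length >= f1.caliper_length - 1e-9
    assert f2.width >= f1.width and f2.height >= f1.height


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000), st.integers(1, 6), st.integers(1, 6))
def test_translation_invariance(seed, dy, dx):
    rng = np.random.default_rng(seed)
    m = np.zeros((24, 24), bool)
    m[2:16, 2:16] = random_mask(rng)
    shifted = np.roll(np.roll(m, dy, axis=0), dx, axis=1)
    f1, f2 = extract_features(m), extract_features(shifted)
    assert f1.as_dict() == pytest.approx(f2.as_dict(), abs=1e-9)
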