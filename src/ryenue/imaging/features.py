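"""Silhouette shape features for binary plant masks.

Seven measurements are computed per mask: projected area (pixel count),
caliper length (diameter of the convex hull), compactness (area / hull area),
convex hull area and circumference, and axis-aligned width and height.

Geometry convention: the convex hull is built over the four *corner points*
of every foreground pixel (pixel (r, c) contributes (c, r), (c+1, r),
(c, r+1), (c+1, r+1) in x = column, y = row coordinates).  With this
convention the hull area of any pixel set is at least the pixel count, so
compactness = area / hull_area always lies in (0, 1], with equality exactly
for "pixel-convex" shapes such as filled rectangles.  Hull circumference is
the polygon perimeter of that corner-point hull; width and height are the
whole-pixel extents of the foreground bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from ..errors import EmptyMaskError
from .segment import PlantMask


@dataclass(frozen=True)
class ShapeFeatures:
    area: float
    caliper_length: float
    compactness: float
    convex_hull_area: float
    convex_hull_circumference: float
    width: int
    height: int

    def as_dict(self) -> dict[str, float]:
        return {
            "area": self.area,
            "caliper_length": self.caliper_length,
            "compactness": self.compactness,
            "convex_hull_area": self.convex_hull_area,
            "convex_hull_circumference": self.convex_hull_circumference,
            "width": self.width,
            "height": self.height,
        }


FEATURE_NAMES = (
    "area",
    "caliper_length",
    "compactness",
    "convex_hull_area",
    "convex_hull_circumference",
    "width",
    "height",
)


def pixel_corner_points(grid: np.ndarray) -> np.ndarray:
    """Unique corner points (x, y) of all foreground pixels."""
    rows, cols = np.nonzero(np.asarray(grid, bool))
    if rows.size == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    x = cols.astype(np.float64)
    y = rows.astype(np.float64)
    corners = np.concatenate(
        [
            np.stack([x, y], axis=1),
            np.stack([x + 1, y], axis=1),
            np.stack([x, y + 1], axis=1),
            np.stack([x + 1, y + 1], axis=1),
        ]
    )
    return np.unique(corners, axis=0)


def convex_hull_vertices(points: np.ndarray) -> np.ndarray:
    """Hull vertices in counter-clockwise order (image x/y coordinates)."""
    hull = ConvexHull(points)
    return points[hull.vertices]


def rotating_calipers_diameter(vertices: np.ndarray) -> float:
    """Diameter of a convex polygon via the rotating-calipers antipodal scan.

    ``vertices`` must be the hull vertices in counter-clockwise order.  Runs
    in O(h) for h vertices.
    """
    pts = np.asarray(vertices, dtype=np.float64)
    k = len(pts)
    if k == 1:
        return 0.0
    if k == 2:
        return float(np.hypot(*(pts[1] - pts[0])))

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    best = 0.0
    j = 1
    for i in range(k):
        ni = (i + 1) % k
        # advance the antipodal pointer while the triangle area keeps growing
        while abs(cross(pts[i], pts[ni], pts[(j + 1) % k])) > abs(
            cross(pts[i], pts[ni], pts[j])
        ):
            j = (j + 1) % k
        for p in (pts[i], pts[ni]):
            d = float(np.hypot(p[0] - pts[j][0], p[1] - pts[j][1]))
            if d > best:
                best = d
    return best


def extract_features(mask: PlantMask | np.ndarray) -> ShapeFeatures:
    """Compute the seven shape features for a non-empty mask.

    Raises :class:`EmptyMaskError` for an empty mask — callers that tolerate
    missing plants should check the mask's ``empty`` flag first.
    """
    grid = mask.grid if isinstance(mask, PlantMask) else np.asarray(mask, bool)
    rows, cols = np.nonzero(grid)
    if rows.size == 0:
        raise EmptyMaskError("cannot extract features from an empty mask")

    area = float(rows.size)
    width = int(cols.max() - cols.min() + 1)
    height = int(rows.max() - rows.min() + 1)

    corners = pixel_corner_points(grid)
    hull = ConvexHull(corners)
    hull_area = float(hull.volume)      # 2-D: volume is the polygon area
    hull_perimeter = float(hull.area)   # 2-D: area is the polygon perimeter
    vertices = corners[hull.vertices]
    caliper = rotating_calipers_diameter(vertices)

    return ShapeFeatures(
        area=area,
        caliper_length=caliper,
        compactness=area / hull_area,
        convex_hull_area=hull_area,
        convex_hull_circumference=hull_perimeter,
        width=width,
        height=height,
    )
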