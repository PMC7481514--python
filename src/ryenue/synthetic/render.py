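"""Render multi-view RGB images (plus ground-truth masks) of a plant model.

Three views mirror an imaging cabinet: ``top`` (projection onto the pot
plane), ``side-0`` and ``side-90`` (two horizontal views 90 degrees apart;
the side-90 geometry is the side-0 geometry rotated about the vertical
axis).  Plant pixels are green-dominant by construction — G exceeds both R
and B by at least 30 on the 0-255 scale — so an excess-green segmenter can
always recover them; the background emulates a white pot on a neutral grey
cabinet.  The returned mask is exactly the set of rendered plant pixels.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as _label

from ..errors import FrameOverflowError, InvalidArgumentError
from .plants import PlantSpec

VIEWS = ("top", "side-0", "side-90")

#: minimum green dominance of plant pixels: G >= R + 30 and G >= B + 30
GREEN_MARGIN = 30

_N_ARC = 12  # centerline samples per blade


def _blade_centerline(tiller) -> np.ndarray:
    """3-D centerline points (x, y, z) of one blade; z is height above the
    crown, x/y lie in the pot plane."""
    s = np.linspace(0.0, tiller.length, _N_ARC)
    horiz = s * np.cos(tiller.elevation) + tiller.curvature * s**2 / max(tiller.length, 1.0)
    z = s * np.sin(tiller.elevation) - tiller.curvature * s**2 / max(tiller.length, 1.0)
    z = np.maximum(z, 0.0)
    x = horiz * np.cos(tiller.azimuth)
    y = horiz * np.sin(tiller.azimuth)
    return np.stack([x, y, z], axis=1)


def _project(points: np.ndarray, view: str) -> np.ndarray:
    """Project 3-D points to the 2-D (u, v) plane of a view; v grows with
    height for side views."""
    if view == "top":
        return points[:, :2]
    if view == "side-0":
        return np.stack([points[:, 0], points[:, 2]], axis=1)
    if view == "side-90":
        return np.stack([points[:, 1], points[:, 2]], axis=1)
    raise InvalidArgumentError(f"unknown view {view!r}")


def _blade_polygon(center2d: np.ndarray, basal_width: float) -> np.ndarray:
    """Thicken a projected centerline into a tapered polygon."""
    d = np.gradient(center2d, axis=0)
    norm = np.hypot(d[:, 0], d[:, 1])
    norm[norm == 0] = 1.0
    # unit normals to the centerline
    nx = -d[:, 1] / norm
    ny = d[:, 0] / norm
    # floor the half-width so discretised tips stay connected (no sub-pixel
    # fragments that a minimum-size filter would treat as specks)
    taper = np.maximum(np.linspace(1.0, 0.08, len(center2d)) * basal_width / 2.0, 0.8)
    left = center2d + np.stack([nx * taper, ny * taper], axis=1)
    right = center2d - np.stack([nx * taper, ny * taper], axis=1)
    return np.concatenate([left, right[::-1]], axis=0)


def render_plant(
    spec: PlantSpec,
    view: str,
    image_size: int = 400,
    background_style: str = "cabinet",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one view of a plant.

    Returns ``(image, mask)``: an (H, W, 3) uint8 RGB image and the exact
    boolean foreground mask.  Identical arguments give bit-identical output.
    Raises :class:`FrameOverflowError` if any blade projects outside the
    frame — plants are never silently cropped.
    """
    if view not in VIEWS:
        raise InvalidArgumentError(f"view must be one of {VIEWS}")
    if background_style not in ("cabinet", "plain"):
        raise InvalidArgumentError("background_style must be 'cabinet' or 'plain'")
    H = W = int(image_size)
    rng = np.random.default_rng(seed)

    # --- background -------------------------------------------------------
    image = np.empty((H, W, 3), dtype=np.uint8)
    if background_style == "cabinet":
        grad = np.linspace(185, 205, H).astype(np.uint8)[:, None]
        image[:] = np.repeat(grad, W, axis=1)[..., None]
    else:
        image[:] = 235

    pot_h = int(0.15 * H)
    if view == "top":
        rr, cc = draw_disk((H / 2.0, W / 2.0), 0.42 * min(H, W), shape=(H, W))
        image[rr, cc] = (245, 245, 242)
        origin = np.array([W / 2.0, H / 2.0])
    else:
        image[H - pot_h :, :, :] = (240, 240, 238)  # white pot band
        origin = np.array([W / 2.0, H - pot_h])

    # --- plant ------------------------------------------------------------
    background = image.copy()
    mask = np.zeros((H, W), dtype=bool)
    crown3d = np.array([spec.crown[0], spec.crown[1], 0.0])
    for tiller in spec.tillers:
        pts3d = _blade_centerline(tiller) + crown3d
        proj = _project(pts3d, view)
        if view == "top":
            uv = origin + proj
        else:
            # image v axis points down; height grows upwards from the pot rim
            uv = np.stack([origin[0] + proj[:, 0], origin[1] - proj[:, 1]], axis=1)
        poly = _blade_polygon(uv, tiller.basal_width)
        if poly[:, 0].min() < 0 or poly[:, 0].max() >= W or poly[:, 1].min() < 0 or poly[:, 1].max() >= H:
            raise FrameOverflowError(
                f"blade projects outside the {W}x{H} frame in view {view}"
            )
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(H, W))
        mask[rr, cc] = True
        g = int(rng.integers(150, 215))
        r = int(np.clip(rng.integers(35, 90), 0, g - GREEN_MARGIN))
        b = int(np.clip(rng.integers(40, 105), 0, g - GREEN_MARGIN))
        image[rr, cc] = (r, g, b)

    # polygon rasterisation of near-degenerate blade tips can strand a few
    # isolated pixels; unpaint any component below 8 px so the rendered
    # plant (and hence the ground-truth mask) carries no specks
    lab = _label(mask, connectivity=2)
    sizes = np.bincount(lab.ravel())
    small = (sizes < 8) & (np.arange(sizes.size) > 0)
    if small.any():
        speck = small[lab]
        mask[speck] = False
        image[speck] = background[speck]

    return image, mask


def render_views(
    spec: PlantSpec, image_size: int = 400, seed: int = 0
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Render all three views with per-view sub-seeds."""
    return {
        v: render_plant(spec, v, image_size=image_size, seed=seed + i)
        for i, v in enumerate(VIEWS)
    }
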