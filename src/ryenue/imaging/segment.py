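"""Plant/background segmentation for multi-view RGB pot images.

Foreground is defined by the excess-green index ExG = 2G - R - B, a standard
colour index that separates green vegetation from neutral backgrounds (white
pots, grey imaging-cabinet walls).  The threshold is either fixed or chosen
automatically by Otsu's method on the ExG channel; morphological opening and
closing and a minimum connected-component size clean up impulse noise.  All
parameters are explicit so the recipe is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk, opening


@dataclass(frozen=True)
class SegmentationParams:
    """Settings for :func:`segment_plant`.

    threshold
        Fixed ExG threshold (foreground strictly above it).  The default of
        20 sits midway between a neutral background (|ExG| near 0) and any
        usefully green pixel; ``None`` selects the threshold automatically
        with Otsu's method instead (useful for imagery with a tinted
        background, but unreliable when the background is nearly uniform —
        Otsu may then split the vegetation class itself).
    opening_radius, closing_radius
        Disk structuring-element radii for binary opening / closing; 0 skips
        the step.  Opening is applied before closing.
    min_size
        Connected components with fewer pixels are dropped (8-connectivity).
    exclusion_zone
        Optional ``(row0, col0, row1, col1)`` half-open rectangle forced to
        background, for masking pot carriers in real imagery.
    """

    threshold: float | None = 20.0
    opening_radius: int = 0
    closing_radius: int = 0
    min_size: int = 4
    exclusion_zone: tuple[int, int, int, int] | None = None


@dataclass
class PlantMask:
    """Binary foreground raster for one plant view.

    ``empty`` is an explicit flag (not an exception) so a failed segmentation
    can be recorded as a missing observation downstream.
    """

    grid: np.ndarray
    empty: bool
    pot_id: str | None = None
    view: str | None = None
    timestamp: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")


def excess_green(image: np.ndarray) -> np.ndarray:
    """ExG = 2G - R - B on an (H, W, 3) uint8 image, as int16."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    r = img[..., 0].astype(np.int16)
    g = img[..., 1].astype(np.int16)
    b = img[..., 2].astype(np.int16)
    return 2 * g - r - b


def segment_plant(
    image: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    *,
    pot_id: str | None = None,
    view: str | None = None,
    timestamp: float | None = None,
) -> PlantMask:
    """Segment one plant from an RGB view image.

    Returns a :class:`PlantMask`; a scene with no plant pixels yields an
    empty-flagged mask rather than raising.
    """
    exg = excess_green(image)

    if params.threshold is not None:
        thr = float(params.threshold)
    else:
        # Otsu needs contrast; a flat ExG channel means no vegetation signal.
        if int(exg.max()) - int(exg.min()) < 2:
            return PlantMask(np.zeros(exg.shape, bool), True, pot_id, view, timestamp)
        thr = float(threshold_otsu(exg))

    fg = exg > thr

    if params.exclusion_zone is not None:
        r0, c0, r1, c1 = params.exclusion_zone
        fg[r0:r1, c0:c1] = False

    if params.opening_radius > 0:
        fg = opening(fg, disk(params.opening_radius))
    if params.closing_radius > 0:
        fg = closing(fg, disk(params.closing_radius))
    if params.min_size > 1:
        lab = label(fg, connectivity=2)
        sizes = np.bincount(lab.ravel())
        keep = sizes >= params.min_size
        keep[0] = False
        fg = keep[lab]

    empty = not bool(fg.any())
    return PlantMask(fg, empty, pot_id, view, timestamp)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (1.0 if both empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
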