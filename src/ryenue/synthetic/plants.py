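"""Procedural 3-D plant model for rendering grass silhouettes.

A plant is a crown at the pot surface plus a set of tillers; each tiller is
a single tapered, gently drooping blade described by its length, basal
width, curvature (droop), azimuth and elevation.  The model is deliberately
schematic — it exists to exercise segmentation and shape-feature code with
fully known ground truth, not to be photorealistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidArgumentError


@dataclass(frozen=True)
class Tiller:
    length: float          # blade length along its arc, px
    basal_width: float     # width at the crown, px (tapers to ~0 at the tip)
    curvature: float       # droop coefficient, fraction of length
    azimuth: float         # radians, horizontal direction
    elevation: float       # radians above horizontal at the base


@dataclass(frozen=True)
class PlantSpec:
    tillers: tuple[Tiller, ...]
    crown: tuple[float, float] = (0.0, 0.0)  # pot-plane offset of the crown, px

    def __post_init__(self) -> None:
        if len(self.tillers) < 1:
            raise InvalidArgumentError("a plant needs at least one tiller")
        for t in self.tillers:
            if t.length <= 0 or t.basal_width <= 0:
                raise InvalidArgumentError("blade dimensions must be positive")

    @property
    def true_volume(self) -> float:
        """Sum over tillers of length x mean width x nominal 1 px thickness."""
        return float(sum(t.length * (t.basal_width / 2.0) for t in self.tillers))


# Empirical constant linking sum(length * mean width) to the rendered
# side-view silhouette area (accounts for elevation foreshortening and
# blade overlap at the crown); measured once on the default renderer.
_SIDE_AREA_PER_VOLUME = 0.72


def sample_plant_spec(
    target_side_area: float,
    seed: int,
    *,
    max_length: float = 170.0,
    min_tillers: int = 3,
    max_tillers: int = 70,
) -> PlantSpec:
    """Draw a random plant whose side-view silhouette area is roughly
    ``target_side_area`` pixels.

    Tiller count scales with the target area at a fixed mean blade size, so
    bigger plants are bushier rather than uniformly scaled-up.
    """
    if target_side_area <= 0:
        raise InvalidArgumentError("target area must be positive")
    rng = np.random.default_rng(seed)

    mean_len = 0.65 * max_length
    mean_width = 5.0
    per_tiller = _SIDE_AREA_PER_VOLUME * mean_len * mean_width / 2.0
    n = int(np.clip(round(target_side_area / per_tiller), min_tillers, max_tillers))

    tillers = []
    for k in range(n):
        length = float(np.clip(rng.normal(mean_len, 0.15 * mean_len), 20.0, max_length))
        width = float(np.clip(rng.normal(mean_width, 1.0), 2.5, 9.0))
        curvature = float(rng.uniform(0.1, 0.35))
        azimuth = float(rng.uniform(0.0, 2.0 * np.pi))
        elevation = float(rng.uniform(np.deg2rad(45.0), np.deg2rad(85.0)))
        tillers.append(Tiller(length, width, curvature, azimuth, elevation))
    crown = tuple(rng.uniform(-4.0, 4.0, 2))
    return PlantSpec(tillers=tuple(tillers), crown=crown)
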