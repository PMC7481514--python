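"""Destructive-harvest simulation: fresh and dry biomass per pot per phase.

Biomass is coupled linearly to the silhouette area a cut removes: the fresh
mass of the clipped material is proportional to (area at cut - residual A0),
with multiplicative lognormal noise; dry mass is a treatment-specific dry
matter fraction of fresh mass, again with noise.  Noise standard deviations
default to a calibration under which the realized Pearson correlation
between mean projected plant area and fresh biomass across a full trial is
about 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import InvalidArgumentError
from .growth import GrowthTruth, PHASES


@dataclass(frozen=True)
class HarvestModel:
    """Parameters of the area -> biomass coupling.

    fm_per_pixel: g fresh mass per pixel of harvested silhouette area.
    dm_fraction: dry matter fraction of fresh mass, per treatment (mM).
    fm_noise_sd / dm_noise_sd: lognormal sigmas of the multiplicative noise.
    """

    fm_per_pixel: float = 8.5e-5
    dm_fraction: dict[float, float] | None = None
    fm_noise_sd: float = 0.135
    dm_noise_sd: float = 0.04

    def dm_frac(self, treatment: float) -> float:
        if self.dm_fraction is None:
            return 0.20
        return self.dm_fraction[treatment]


def simulate_harvests(
    phase_ends: pd.DataFrame,
    truth: GrowthTruth,
    model: HarvestModel = HarvestModel(),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate one harvest record per pot per phase.

    ``phase_ends`` is the output of :func:`ryenue.synthetic.growth.phase_end_areas`
    and must span all three phases.  Returns columns ``pot_id, genotype,
    treatment, replicate, phase, phase_duration, FM, DM``.
    """
    missing = set(PHASES) - set(phase_ends["phase"].unique())
    if missing:
        raise InvalidArgumentError(f"phase_ends is missing phases: {sorted(missing)}")
    if model.fm_per_pixel <= 0:
        raise InvalidArgumentError("fm_per_pixel must be positive")

    rng = np.random.default_rng(seed)
    n = len(phase_ends)
    fm_noise = rng.lognormal(0.0, model.fm_noise_sd, n) if model.fm_noise_sd > 0 else np.ones(n)
    dm_noise = rng.lognormal(0.0, model.dm_noise_sd, n) if model.dm_noise_sd > 0 else np.ones(n)

    out = phase_ends[
        ["pot_id", "genotype", "treatment", "replicate", "phase", "phase_duration"]
    ].copy()
    gain = np.maximum(phase_ends["area_end"].to_numpy() - truth.A0, 0.0)
    fm = model.fm_per_pixel * gain * fm_noise
    dm_frac = phase_ends["treatment"].map(model.dm_frac).to_numpy()
    dm = fm * dm_frac * dm_noise
    out["FM"] = fm
    out["DM"] = np.minimum(dm, fm)  # dry mass can never exceed fresh mass
    return out
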