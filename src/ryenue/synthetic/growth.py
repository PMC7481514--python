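"""Logistic regrowth simulation with defoliation resets.

Each pot regrows from a residual area A0 (the silhouette left after cutting
to 5 cm stubble) towards a pot-specific asymptote K, following the logistic
law

    A(t) = K * A0 / (A0 + (K - A0) * exp(-r * t)),   t = days since the cut.

This law is chosen because its absolute growth rate dA/dt rises and then
falls after each defoliation (unimodal, peaking where A = K/2) while its
relative growth rate d ln A / dt decays monotonically — the qualitative
temporal pattern reported for ryegrass regrowth under both N levels.

The asymptote composes treatment, genotype and genotype-by-treatment
effects multiplicatively:

    K_pot = K(treatment) * g(genotype) * i(genotype, treatment)

with an additive replicate block shift applied to observed areas.  During
the acclimation phase (AP) the treatment effect on K is suppressed (both
treatments share the low-N asymptote): freshly transplanted plants still
draw on nitrogen reserves, so the N contrast is not yet expressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import InvalidArgumentError

PHASES = ("AP", "EP-1", "EP-2")

#: Imaging offsets (days after each cut): twice-weekly, 8 dates per 28-day
#: phase, kept strictly inside the phase so phase assignment is unambiguous.
DEFAULT_IMAGING_OFFSETS = (3.0, 7.0, 10.0, 14.0, 17.0, 21.0, 24.0, 27.0)

DEFAULT_CUT_DATES = (28.0, 56.0, 84.0)


def logistic_area(t: np.ndarray | float, K: float, A0: float, r: float) -> np.ndarray:
    """Closed-form logistic regrowth from A0 towards K at rate r (d^-1)."""
    t = np.asarray(t, dtype=float)
    return K * A0 / (A0 + (K - A0) * np.exp(-r * t))


def logistic_agr(t: np.ndarray | float, K: float, A0: float, r: float) -> np.ndarray:
    """Analytic absolute growth rate dA/dt of the logistic law."""
    a = logistic_area(t, K, A0, r)
    return r * a * (1.0 - a / K)


def logistic_rgr(t: np.ndarray | float, K: float, A0: float, r: float) -> np.ndarray:
    """Analytic relative growth rate d ln A / dt of the logistic law."""
    a = logistic_area(t, K, A0, r)
    return r * (1.0 - a / K)


@dataclass
class GrowthTruth:
    """Ground-truth parameters generating a synthetic trial.

    Units: areas in pixels (projected side-view area), rates in d^-1.
    ``K`` maps treatment level (mM N) to the population asymptote;
    ``genotype_multipliers`` (mean ~1, lognormal) scale K per genotype;
    ``interaction_multipliers[g, t]`` add genotype-by-treatment structure;
    ``replicate_effects`` are additive pixel shifts per block.
    """

    K: dict[float, float]
    r: float
    A0: float
    genotype_multipliers: np.ndarray
    interaction_multipliers: np.ndarray
    replicate_effects: np.ndarray
    treatments: tuple[float, ...]
    obs_noise_sd: float = 0.05
    ap_equalized: bool = True

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise InvalidArgumentError("A0 must be positive")
        if np.any(self.genotype_multipliers <= 0) or np.any(
            self.interaction_multipliers <= 0
        ):
            raise InvalidArgumentError("multipliers must be positive")

    def asymptote(self, genotype: int, treatment: float, phase: str) -> float:
        """Pot-level K for a genotype/treatment in a given phase."""
        t_idx = self.treatments.index(treatment)
        if phase == "AP" and self.ap_equalized:
            base = self.K[min(self.treatments)]
        else:
            base = self.K[treatment]
        g = self.genotype_multipliers[genotype - 1]
        i = self.interaction_multipliers[genotype - 1, t_idx]
        return float(base * g * i)


def sample_growth_truth(
    n_genotypes: int = 76,
    treatments: tuple[float, ...] = (0.5, 5.0),
    n_replicates: int = 4,
    *,
    K_by_treatment: dict[float, float] | None = None,
    r: float = 0.30,
    A0: float = 6000.0,
    genotype_sd: float = 0.28,
    interaction_sd: float = 0.08,
    replicate_sd: float = 800.0,
    obs_noise_sd: float = 0.05,
    seed: int = 0,
) -> GrowthTruth:
    """Draw trial-level ground truth.

    Defaults give asymptotes of ~8e4 px under 0.5 mM and ~1.6e5 px under
    5 mM N (a two-fold contrast, matching the roughly doubled growth rates
    observed under moderate N) with lognormal genotype and interaction
    multipliers and small additive replicate shifts.
    """
    rng = np.random.default_rng(seed)
    if K_by_treatment is None:
        lo = min(treatments)
        K_by_treatment = {t: 80_000.0 * (2.0 if t != lo else 1.0) for t in treatments}
    g_mult = np.exp(rng.normal(0.0, genotype_sd, n_genotypes))
    i_mult = np.exp(rng.normal(0.0, interaction_sd, (n_genotypes, len(treatments))))
    rep_eff = rng.normal(0.0, replicate_sd, n_replicates)
    return GrowthTruth(
        K=dict(K_by_treatment),
        r=r,
        A0=A0,
        genotype_multipliers=g_mult,
        interaction_multipliers=i_mult,
        replicate_effects=rep_eff,
        treatments=tuple(treatments),
        obs_noise_sd=obs_noise_sd,
    )


def _phase_bounds(cut_dates: tuple[float, ...]) -> list[tuple[str, float, float]]:
    if len(cut_dates) != 3:
        raise InvalidArgumentError("exactly three cut dates are required")
    if not all(b > a for a, b in zip(cut_dates, cut_dates[1:])) or cut_dates[0] <= 0:
        raise InvalidArgumentError("cut dates must be strictly increasing and positive")
    starts = (0.0, *cut_dates[:-1])
    return [(ph, s, c) for ph, s, c in zip(PHASES, starts, cut_dates)]


def simulate_growth(
    design: pd.DataFrame,
    truth: GrowthTruth,
    cut_dates: tuple[float, ...] = DEFAULT_CUT_DATES,
    imaging_offsets: tuple[float, ...] = DEFAULT_IMAGING_OFFSETS,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-pot area trajectories across the three regrowth phases.

    Returns a long table with one row per pot x imaging date:
    ``pot_id, genotype, treatment, replicate, timestamp, phase,
    days_since_cut, true_area, area_side0, area_side90, area_top``.
    Observed per-view areas carry multiplicative lognormal noise and the
    additive replicate shift; the top view projects a denser, partially
    self-occluded canopy and is scaled to 60% of the side area.
    """
    bounds = _phase_bounds(tuple(cut_dates))
    offsets = np.asarray(imaging_offsets, dtype=float)
    if np.any(offsets <= 0):
        raise InvalidArgumentError("imaging offsets must be positive days after a cut")

    rng = np.random.default_rng(seed)
    rows = []
    for pot in design.itertuples(index=False):
        rep_shift = truth.replicate_effects[pot.replicate - 1]
        for phase, start, cut in bounds:
            K = truth.asymptote(pot.genotype, pot.treatment, phase)
            in_phase = offsets[start + offsets < cut]
            true_area = logistic_area(in_phase, K, truth.A0, truth.r)
            for dt, a in zip(in_phase, true_area):
                noise = rng.lognormal(0.0, truth.obs_noise_sd, 3) if truth.obs_noise_sd > 0 else np.ones(3)
                side0 = max(a * noise[0] + rep_shift, 1.0)
                side90 = max(a * noise[1] + rep_shift, 1.0)
                top = max(0.6 * a * noise[2] + 0.6 * rep_shift, 1.0)
                rows.append(
                    {
                        "pot_id": pot.pot_id,
                        "genotype": pot.genotype,
                        "treatment": pot.treatment,
                        "replicate": pot.replicate,
                        "timestamp": start + dt,
                        "phase": phase,
                        "days_since_cut": dt,
                        "true_area": a,
                        "area_side0": side0,
                        "area_side90": side90,
                        "area_top": top,
                    }
                )
    return pd.DataFrame(rows)


def phase_end_areas(
    design: pd.DataFrame,
    truth: GrowthTruth,
    cut_dates: tuple[float, ...] = DEFAULT_CUT_DATES,
) -> pd.DataFrame:
    """Noise-free true area at each cut date (the material removed is
    ``area_end - A0``); used to couple harvest biomass to growth."""
    bounds = _phase_bounds(tuple(cut_dates))
    rows = []
    for pot in design.itertuples(index=False):
        for phase, start, cut in bounds:
            K = truth.asymptote(pot.genotype, pot.treatment, phase)
            a_end = float(logistic_area(cut - start, K, truth.A0, truth.r))
            rows.append(
                {
                    "pot_id": pot.pot_id,
                    "genotype": pot.genotype,
                    "treatment": pot.treatment,
                    "replicate": pot.replicate,
                    "phase": phase,
                    "phase_start": start,
                    "cut_date": cut,
                    "phase_duration": cut - start,
                    "area_end": a_end,
                }
            )
    return pd.DataFrame(rows)
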