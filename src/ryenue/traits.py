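"""Derived digital-biomass traits and growth analysis.

From the per-view feature table this module derives, per pot:

* MPPA — mean projected plant area, the arithmetic mean of the two
  side-view silhouette areas (pixels);
* three digital volumes combining the three view areas,
  V = As0 + As90 + At (sum), V_lemnatec = As0 * As90 * At (product) and
  V_keygene = As0 + As90 + 3 ln(At) (side sum plus log-compressed top area);
* phase-level and per-interval growth rates on MPPA:
  AGR = (MPPA2 - MPPA1) / (t2 - t1)  (pixel d^-1) and
  RGR = (ln MPPA2 - ln MPPA1) / (t2 - t1)  (d^-1);
* supplied nitrogen mass Ns from the nutrient schedule and nitrogen use
  efficiency NUE = DM / Ns (g dry matter per g N).

Timestamps are real-valued days since the start of the experiment; the
three regrowth phases AP, EP-1 and EP-2 are the half-open intervals between
consecutive defoliation cuts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

log = logging.getLogger(__name__)

PHASES = ("AP", "EP-1", "EP-2")
OUT_OF_STUDY = "out-of-study"

#: molar mass of elemental nitrogen, g per mmol
N_MOLAR_MASS = 0.014007


def mppa(area_side0: float, area_side90: float) -> float:
    """Mean projected plant area of the two orthogonal side views."""
    if area_side0 < 0 or area_side90 < 0:
        raise InvalidArgumentError("view areas must be non-negative")
    return (area_side0 + area_side90) / 2.0


@dataclass(frozen=True)
class DerivedVolumes:
    V: float
    V_lemnatec: float
    V_keygene: float


def digital_volumes(
    area_side0: float,
    area_side90: float,
    area_top: float,
    *,
    keygene_log: str = "ln",
) -> DerivedVolumes:
    """The three digital-volume biomass proxies from the three view areas.

    ``keygene_log`` selects the logarithm in the keygene variant: ``"ln"``
    (default, 3*ln(At)) or ``"log10"`` (3*log10(At)).
    """
    if area_side0 <= 0 or area_side90 <= 0 or area_top <= 0:
        raise InvalidArgumentError("digital volumes require positive view areas")
    if keygene_log == "ln":
        log_at = math.log(area_top)
    elif keygene_log == "log10":
        log_at = math.log10(area_top)
    else:
        raise InvalidArgumentError("keygene_log must be 'ln' or 'log10'")
    return DerivedVolumes(
        V=area_side0 + area_side90 + area_top,
        V_lemnatec=area_side0 * area_side90 * area_top,
        V_keygene=area_side0 + area_side90 + 3.0 * log_at,
    )


@dataclass(frozen=True)
class NutrientSchedule:
    """Per-phase nutrient application plan for one treatment.

    concentration: mmol elemental N per litre (mM); volume: litres per
    application; n_applications: applications per regrowth phase.
    """

    concentration: float
    volume: float = 0.1
    n_applications: int = 7
    n_molar_mass: float = N_MOLAR_MASS


def n_supplied(schedule: NutrientSchedule) -> float:
    """Grams of elemental N supplied per pot per phase.

    Ns = concentration (mmol/L) x volume (L) x applications x 0.014007 g/mmol.
    """
    if (
        schedule.concentration <= 0
        or schedule.volume <= 0
        or schedule.n_applications <= 0
        or schedule.n_molar_mass <= 0
    ):
        raise InvalidArgumentError("all nutrient-schedule quantities must be positive")
    return (
        schedule.concentration
        * schedule.volume
        * schedule.n_applications
        * schedule.n_molar_mass
    )


def nue(dm: float, ns: float) -> float:
    """Nitrogen use efficiency: g dry matter per g supplied N."""
    if ns <= 0:
        raise InvalidArgumentError("supplied N must be positive")
    if dm < 0:
        raise InvalidArgumentError("dry mass cannot be negative")
    return dm / ns


def assign_phases(
    timestamps: np.ndarray | pd.Series | list[float],
    cut_dates: tuple[float, float, float],
    start: float = 0.0,
) -> np.ndarray:
    """Label each timestamp with its regrowth phase.

    Half-open convention: AP = [start, cut1), EP-1 = [cut1, cut2),
    EP-2 = [cut2, cut3); anything at or after the final cut is labelled
    out-of-study (and logged), anything before ``start`` is invalid.
    """
    cuts = tuple(float(c) for c in cut_dates)
    if len(cuts) != 3 or not all(b > a for a, b in zip(cuts, cuts[1:])):
        raise InvalidArgumentError("exactly 3 strictly increasing cut dates required")
    if start >= cuts[0]:
        raise InvalidArgumentError("experiment start must precede the first cut")
    t = np.asarray(timestamps, dtype=float)
    if np.any(t < start):
        raise InvalidArgumentError("timestamp precedes the experiment start")
    labels = np.full(t.shape, OUT_OF_STUDY, dtype=object)
    edges = (start, *cuts)
    for phase, lo, hi in zip(PHASES, edges[:-1], edges[1:]):
        labels[(t >= lo) & (t < hi)] = phase
    n_out = int((labels == OUT_OF_STUDY).sum())
    if n_out:
        log.warning("%d timestamps fall after the final cut (out-of-study)", n_out)
    return labels


def growth_rates(
    timestamps: np.ndarray | list[float],
    mppa_values: np.ndarray | list[float],
) -> tuple[dict, pd.DataFrame]:
    """Phase-level and per-interval growth rates for one pot-phase series.

    The phase-level rates use the first and last imaging date of the series
    as (t1, t2); per-interval rates are computed between every pair of
    consecutive dates (the temporal AGR/RGR profile).  Returns
    ``(phase_level, intervals)``; RGR is NaN where an endpoint MPPA is not
    positive, while AGR is always computed.
    """
    t = np.asarray(timestamps, dtype=float)
    m = np.asarray(mppa_values, dtype=float)
    if t.size != m.size:
        raise InvalidArgumentError("timestamps and MPPA series differ in length")
    order = np.argsort(t, kind="mergesort")
    t, m = t[order], m[order]
    if t.size < 2:
        raise InvalidArgumentError("need at least two imaging dates")
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("timestamps must be distinct")

    def _rates(t1, t2, m1, m2):
        agr = (m2 - m1) / (t2 - t1)
        if m1 > 0 and m2 > 0:
            rgr = (math.log(m2) - math.log(m1)) / (t2 - t1)
        else:
            rgr = float("nan")
        return agr, rgr

    agr, rgr = _rates(t[0], t[-1], m[0], m[-1])
    phase_level = {
        "t1": float(t[0]),
        "t2": float(t[-1]),
        "MPPA1": float(m[0]),
        "MPPA2": float(m[-1]),
        "AGR_area": float(agr),
        "RGR": float(rgr),
    }
    rows = []
    for i in range(t.size - 1):
        a, r = _rates(t[i], t[i + 1], m[i], m[i + 1])
        rows.append(
            {
                "t1": t[i],
                "t2": t[i + 1],
                "t_mid": 0.5 * (t[i] + t[i + 1]),
                "AGR_area": a,
                "RGR": r,
            }
        )
    return phase_level, pd.DataFrame(rows)


def pivot_view_areas(features: pd.DataFrame) -> pd.DataFrame:
    """Reshape a long per-view feature table to one row per (pot, date) with
    ``area_side0, area_side90, area_top`` columns; empty-flagged views become
    missing values."""
    f = features.copy()
    if "empty_flag" in f.columns:
        f.loc[f["empty_flag"].astype(bool), "area"] = np.nan
    wide = f.pivot_table(
        index=["pot_id", "timestamp"], columns="view", values="area", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    return wide.rename(
        columns={"side-0": "area_side0", "side-90": "area_side90", "top": "area_top"}
    )


def derive_trait_table(
    features: pd.DataFrame,
    harvests: pd.DataFrame,
    schedules: dict[float, NutrientSchedule],
    cut_dates: tuple[float, float, float] = (28.0, 56.0, 84.0),
    *,
    keygene_log: str = "ln",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the per-pot per-phase trait table and per-interval growth table.

    ``features`` is either the image-derived feature table (long, per view)
    or a synthetic view-area table already carrying ``area_side0 /
    area_side90 / area_top`` columns.  ``harvests`` carries FM/DM and the
    phase duration; ``schedules`` maps treatment level (mM) to its nutrient
    schedule.  Per phase, MPPA and the digital volumes are reported at the
    last imaging date of that phase; growth rates span the phase's first to
    last imaging date.  Pots with missing views simply yield missing values
    (logged), never exceptions.
    """
    if {"area_side0", "area_side90"}.issubset(features.columns):
        wide = features.copy()
    else:
        wide = pivot_view_areas(features)
    wide = wide.copy()
    wide["phase"] = assign_phases(wide["timestamp"], cut_dates)
    wide = wide[wide["phase"] != OUT_OF_STUDY]
    wide["MPPA"] = (wide["area_side0"] + wide["area_side90"]) / 2.0

    ns_by_treatment = {trt: n_supplied(s) for trt, s in schedules.items()}

    meta_cols = [c for c in ("genotype", "treatment", "replicate") if c in harvests.columns]
    harvest_idx = harvests.set_index(["pot_id", "phase"])

    phase_rows = []
    interval_rows = []
    for (pot, phase), grp in wide.groupby(["pot_id", "phase"], sort=True):
        grp = grp.sort_values("timestamp")
        last = grp.iloc[-1]
        row: dict = {"pot_id": pot, "phase": phase}
        try:
            hrow = harvest_idx.loc[(pot, phase)]
        except KeyError:
            hrow = None
            log.warning("no harvest record for pot %s phase %s", pot, phase)
        if hrow is not None:
            for c in meta_cols:
                row[c] = hrow[c]

        row["MPPA"] = float(last["MPPA"]) if np.isfinite(last["MPPA"]) else np.nan
        areas = (last.get("area_side0"), last.get("area_side90"), last.get("area_top"))
        if all(a is not None and np.isfinite(a) and a > 0 for a in areas):
            vol = digital_volumes(*map(float, areas), keygene_log=keygene_log)
            row.update(V=vol.V, V_lemnatec=vol.V_lemnatec, V_keygene=vol.V_keygene)
        else:
            row.update(V=np.nan, V_lemnatec=np.nan, V_keygene=np.nan)

        valid = grp[np.isfinite(grp["MPPA"])]
        if len(valid) >= 2:
            phase_level, intervals = growth_rates(
                valid["timestamp"].to_numpy(), valid["MPPA"].to_numpy()
            )
            row.update(
                AGR_area=phase_level["AGR_area"],
                RGR=phase_level["RGR"],
                t1=phase_level["t1"],
                t2=phase_level["t2"],
            )
            intervals.insert(0, "pot_id", pot)
            intervals.insert(1, "phase", phase)
            interval_rows.append(intervals)
        else:
            log.warning("pot %s phase %s has <2 usable imaging dates", pot, phase)
            row.update(AGR_area=np.nan, RGR=np.nan, t1=np.nan, t2=np.nan)

        if hrow is not None:
            fm, dm = float(hrow["FM"]), float(hrow["DM"])
            duration = float(hrow["phase_duration"])
            row.update(FM=fm, DM=dm, AGR_dm=dm / duration)
            trt = float(hrow["treatment"]) if "treatment" in meta_cols else None
            # NUE is a protocol quantity of the experimental phases only:
            # the acclimation phase exists to exhaust residual N reserves
            if phase != "AP" and trt is not None and trt in ns_by_treatment:
                ns = ns_by_treatment[trt]
                row.update(Ns=ns, NUE=nue(dm, ns))
            else:
                row.update(Ns=np.nan, NUE=np.nan)
        else:
            row.update(FM=np.nan, DM=np.nan, AGR_dm=np.nan, Ns=np.nan, NUE=np.nan)
        phase_rows.append(row)

    traits = pd.DataFrame(phase_rows)
    intervals = (
        pd.concat(interval_rows, ignore_index=True)
        if interval_rows
        else pd.DataFrame(columns=["pot_id", "phase", "t1", "t2", "t_mid", "AGR_area", "RGR"])
    )
    return traits, intervals
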