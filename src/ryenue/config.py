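"""Run configuration: one YAML file controls every stage of the pipeline.

The schema is nested key-value sections (design, schedule, growth, harvest,
imaging, segmentation, stats, seed).  Validation collects *all* violations,
each naming the offending key, rather than stopping at the first.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidArgumentError
from .traits import NutrientSchedule

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "design": {
        "n_genotypes": 76,
        "treatments": [0.5, 5.0],
        "n_replicates": 4,
        "row_capacity": 38,
    },
    "schedule": {
        "cut_dates": [28.0, 56.0, 84.0],
        "imaging_offsets": [3.0, 7.0, 10.0, 14.0, 17.0, 21.0, 24.0, 27.0],
        "nutrient": {"volume": 0.1, "n_applications": 7},
    },
    "growth": {
        "r": 0.30,
        "A0": 6000.0,
        "genotype_sd": 0.28,
        "interaction_sd": 0.08,
        "replicate_sd": 800.0,
        "obs_noise_sd": 0.05,
    },
    "harvest": {
        "fm_per_pixel": 8.5e-5,
        "dm_fraction": 0.20,
        "fm_noise_sd": 0.135,
        "dm_noise_sd": 0.04,
    },
    "imaging": {
        "image_size": 400,
        "render_pots": 4,
        "render_dates_per_phase": 2,
        "background_style": "cabinet",
    },
    "segmentation": {
        "threshold": 20.0,
        "opening_radius": 0,
        "closing_radius": 0,
        "min_size": 4,
    },
    "stats": {
        "responses": ["DM", "NUE", "MPPA"],
        "keygene_log": "ln",
    },
}


@dataclass
class RunConfig:
    """Validated run configuration (see DEFAULT_CONFIG for the schema)."""

    raw: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    def __getitem__(self, key: str):
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the master seed."""
        offsets = {"design": 1, "truth": 2, "growth": 3, "harvest": 4, "render": 5}
        return (self.seed * 1009 + offsets.get(stage, 97)) % (2**31 - 1)

    def schedules(self) -> dict[float, NutrientSchedule]:
        nut = self.raw["schedule"]["nutrient"]
        return {
            float(t): NutrientSchedule(
                concentration=float(t),
                volume=float(nut["volume"]),
                n_applications=int(nut["n_applications"]),
            )
            for t in self.raw["design"]["treatments"]
        }

    def segmentation_params(self):
        from .imaging.segment import SegmentationParams

        seg = self.raw["segmentation"]
        return SegmentationParams(
            threshold=seg.get("threshold"),
            opening_radius=int(seg.get("opening_radius", 0)),
            closing_radius=int(seg.get("closing_radius", 0)),
            min_size=int(seg.get("min_size", 4)),
        )


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def validate_config(config: dict) -> list[str]:
    """Return a list of human-readable violations (empty when valid)."""
    v: list[str] = []

    def _require(section: str, key: str, pred, message: str) -> None:
        sec = config.get(section)
        if not isinstance(sec, dict):
            v.append(f"{section}: missing or not a mapping")
            return
        if key not in sec:
            v.append(f"{section}.{key}: missing")
            return
        try:
            ok = pred(sec[key])
        except (TypeError, ValueError):
            ok = False
        if not ok:
            v.append(f"{section}.{key}: {message} (got {sec[key]!r})")

    if not isinstance(config.get("seed"), int) or config.get("seed", -1) < 0:
        v.append("seed: must be a non-negative integer")

    _require("design", "n_genotypes", lambda x: int(x) >= 1, "must be >= 1")
    _require("design", "n_replicates", lambda x: int(x) >= 1, "must be >= 1")
    _require("design", "row_capacity", lambda x: int(x) >= 1, "must be >= 1")
    _require(
        "design",
        "treatments",
        lambda x: len(x) >= 1 and all(float(t) > 0 for t in x) and len(set(x)) == len(x),
        "must be distinct positive N concentrations (mM)",
    )

    _require(
        "schedule",
        "cut_dates",
        lambda x: len(x) == 3 and all(b > a for a, b in zip(x, x[1:])) and x[0] > 0,
        "must be 3 strictly increasing positive days",
    )
    _require(
        "schedule",
        "imaging_offsets",
        lambda x: len(x) >= 2 and all(float(o) > 0 for o in x),
        "must be >= 2 positive day offsets",
    )
    sched = config.get("schedule", {})
    nut = sched.get("nutrient") if isinstance(sched, dict) else None
    if not isinstance(nut, dict):
        v.append("schedule.nutrient: missing or not a mapping")
    else:
        if not (isinstance(nut.get("volume"), (int, float)) and nut["volume"] > 0):
            v.append(f"schedule.nutrient.volume: must be positive litres (got {nut.get('volume')!r})")
        if not (isinstance(nut.get("n_applications"), int) and nut["n_applications"] >= 1):
            v.append(
                f"schedule.nutrient.n_applications: must be a positive integer (got {nut.get('n_applications')!r})"
            )

    _require("growth", "r", lambda x: float(x) > 0, "must be a positive rate (d^-1)")
    _require("growth", "A0", lambda x: float(x) > 0, "must be a positive residual area")
    for key in ("genotype_sd", "interaction_sd", "replicate_sd", "obs_noise_sd"):
        _require("growth", key, lambda x: float(x) >= 0, "must be >= 0")

    _require("harvest", "fm_per_pixel", lambda x: float(x) > 0, "must be positive")
    _require("harvest", "dm_fraction", lambda x: 0 < float(x) <= 1, "must lie in (0, 1]")
    for key in ("fm_noise_sd", "dm_noise_sd"):
        _require("harvest", key, lambda x: float(x) >= 0, "must be >= 0")

    _require("imaging", "image_size", lambda x: int(x) >= 64, "must be >= 64 px")
    _require("imaging", "render_pots", lambda x: int(x) >= 0, "must be >= 0")
    _require("imaging", "render_dates_per_phase", lambda x: int(x) >= 0, "must be >= 0")
    _require(
        "imaging",
        "background_style",
        lambda x: x in ("cabinet", "plain"),
        "must be 'cabinet' or 'plain'",
    )

    seg = config.get("segmentation", {})
    if isinstance(seg, dict):
        thr = seg.get("threshold")
        if thr is not None and not isinstance(thr, (int, float)):
            v.append(f"segmentation.threshold: must be a number or null (got {thr!r})")
        for key in ("opening_radius", "closing_radius", "min_size"):
            if key in seg and (not isinstance(seg[key], int) or seg[key] < 0):
                v.append(f"segmentation.{key}: must be a non-negative integer (got {seg[key]!r})")
    else:
        v.append("segmentation: missing or not a mapping")

    st = config.get("stats", {})
    if isinstance(st, dict) and st.get("keygene_log") not in ("ln", "log10"):
        v.append(f"stats.keygene_log: must be 'ln' or 'log10' (got {st.get('keygene_log')!r})")

    return v


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a config file (missing keys fall back to defaults).

    Raises :class:`InvalidArgumentError` listing every violation.
    """
    merged = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise InvalidArgumentError(f"config file {path} is not a mapping")
        merged = _merge(merged, user)
    if overrides:
        merged = _merge(merged, overrides)
    violations = validate_config(merged)
    if violations:
        raise InvalidArgumentError(
            "invalid configuration:\n  " + "\n  ".join(violations)
        )
    return RunConfig(raw=merged)


def write_default_config(path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(DEFAULT_CONFIG, fh, sort_keys=False)
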