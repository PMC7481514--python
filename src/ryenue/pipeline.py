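"""End-to-end orchestration: simulate -> extract -> derive -> analyze.

Each stage reads only on-disk artifacts of the previous stage, so stages
can be re-run independently.  A JSON manifest records inputs, outputs,
seeds, the package version and a SHA-256 checksum of every artifact;
identical config + seed produce identical checksums.

The growth/harvest simulation always covers the full trial; images are
rendered for a configurable subset of pots and dates (rendering every pot
at every date would dwarf the statistical content of a run), and the
simulate stage additionally writes the full trial's per-view areas in the
same wide schema the derive stage accepts, so trial-level statistics never
depend on the rendered subset.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import InvalidArgumentError
from .imaging.batch import batch_extract
from .stats import correlate, fit_blues_by_phase, recover_parameters, summarize
from .synthetic import (
    GrowthTruth,
    HarvestModel,
    generate_design,
    phase_end_areas,
    render_views,
    sample_growth_truth,
    sample_plant_spec,
    simulate_growth,
    simulate_harvests,
)
from .traits import derive_trait_table

log = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "derive", "analyze")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    d = cfg["design"]
    sch = cfg["schedule"]
    gr = cfg["growth"]
    hv = cfg["harvest"]

    design = generate_design(
        n_genotypes=int(d["n_genotypes"]),
        treatments=tuple(float(t) for t in d["treatments"]),
        n_replicates=int(d["n_replicates"]),
        row_capacity=int(d["row_capacity"]),
        seed=cfg.stage_seed("design"),
    )
    truth = sample_growth_truth(
        n_genotypes=int(d["n_genotypes"]),
        treatments=tuple(float(t) for t in d["treatments"]),
        n_replicates=int(d["n_replicates"]),
        r=float(gr["r"]),
        A0=float(gr["A0"]),
        genotype_sd=float(gr["genotype_sd"]),
        interaction_sd=float(gr["interaction_sd"]),
        replicate_sd=float(gr["replicate_sd"]),
        obs_noise_sd=float(gr["obs_noise_sd"]),
        seed=cfg.stage_seed("truth"),
    )
    cut_dates = tuple(float(c) for c in sch["cut_dates"])
    offsets = tuple(float(o) for o in sch["imaging_offsets"])
    trajectories = simulate_growth(
        design, truth, cut_dates, offsets, seed=cfg.stage_seed("growth")
    )
    ends = phase_end_areas(design, truth, cut_dates)
    model = HarvestModel(
        fm_per_pixel=float(hv["fm_per_pixel"]),
        dm_fraction={float(t): float(hv["dm_fraction"]) for t in d["treatments"]},
        fm_noise_sd=float(hv["fm_noise_sd"]),
        dm_noise_sd=float(hv["dm_noise_sd"]),
    )
    harvests = simulate_harvests(ends, truth, model, seed=cfg.stage_seed("harvest"))

    written = []
    for name, df in [
        ("design.csv", design),
        ("trajectories.csv", trajectories),
        ("harvests.csv", harvests),
    ]:
        _write_csv(df, out / name)
        written.append(out / name)

    truth_json = {
        "seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s) for s in ("design", "truth", "growth", "harvest", "render")},
        "K": {str(k): v for k, v in truth.K.items()},
        "r": truth.r,
        "A0": truth.A0,
        "treatments": list(truth.treatments),
        "genotype_multipliers": truth.genotype_multipliers.tolist(),
        "interaction_multipliers": truth.interaction_multipliers.tolist(),
        "replicate_effects": truth.replicate_effects.tolist(),
        "obs_noise_sd": truth.obs_noise_sd,
        "harvest_model": {
            "fm_per_pixel": model.fm_per_pixel,
            "dm_fraction": {str(k): v for k, v in (model.dm_fraction or {}).items()},
            "fm_noise_sd": model.fm_noise_sd,
            "dm_noise_sd": model.dm_noise_sd,
        },
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    written.append(truth_path)

    written += _render_subset(cfg, out, trajectories)
    return written


def _render_subset(cfg: RunConfig, out: Path, trajectories: pd.DataFrame) -> list[Path]:
    im = cfg["imaging"]
    n_pots = int(im["render_pots"])
    dates_per_phase = int(im["render_dates_per_phase"])
    if n_pots == 0 or dates_per_phase == 0:
        return []
    pots = sorted(trajectories["pot_id"].unique())[:n_pots]
    written: list[Path] = []
    base_seed = cfg.stage_seed("render")
    for pi, pot in enumerate(pots):
        traj = trajectories[trajectories["pot_id"] == pot]
        for phase, grp in traj.groupby("phase", sort=True):
            dates = grp.sort_values("timestamp").iloc[
                np.linspace(0, len(grp) - 1, dates_per_phase).astype(int)
            ]
            for di, row in enumerate(dates.itertuples(index=False)):
                seed = (base_seed + 7919 * pi + 31 * int(row.timestamp * 10) + di) % (2**31 - 1)
                spec = sample_plant_spec(
                    target_side_area=float(row.area_side0),
                    seed=seed,
                    max_length=0.42 * int(im["image_size"]),
                )
                views = render_views(spec, image_size=int(im["image_size"]), seed=seed)
                date_dir = out / "images" / pot / f"{row.timestamp:g}"
                mask_dir = out / "masks" / pot / f"{row.timestamp:g}"
                date_dir.mkdir(parents=True, exist_ok=True)
                mask_dir.mkdir(parents=True, exist_ok=True)
                for view, (img, mask) in views.items():
                    iio.imwrite(date_dir / f"{view}.png", img)
                    iio.imwrite(mask_dir / f"{view}.png", mask.astype(np.uint8) * 255)
                    written += [date_dir / f"{view}.png", mask_dir / f"{view}.png"]
    return written


def stage_extract(cfg: RunConfig, out: Path) -> list[Path]:
    image_root = out / "images"
    if not image_root.is_dir():
        raise InvalidArgumentError(
            f"{image_root} does not exist; run the simulate stage first"
        )
    table = batch_extract(image_root, cfg.segmentation_params())
    path = out / "features_image.csv"
    _write_csv(table, path)
    return [path]


def stage_derive(cfg: RunConfig, out: Path) -> list[Path]:
    traj_path = out / "trajectories.csv"
    harvest_path = out / "harvests.csv"
    for p in (traj_path, harvest_path):
        if not p.exists():
            raise InvalidArgumentError(f"{p} does not exist; run the simulate stage first")
    trajectories = pd.read_csv(traj_path)
    harvests = pd.read_csv(harvest_path)
    cut_dates = tuple(float(c) for c in cfg["schedule"]["cut_dates"])
    traits, intervals = derive_trait_table(
        trajectories,
        harvests,
        cfg.schedules(),
        cut_dates,
        keygene_log=cfg["stats"]["keygene_log"],
    )
    written = []
    for name, df in [("traits.csv", traits), ("growth_intervals.csv", intervals)]:
        _write_csv(df, out / name)
        written.append(out / name)
    return written


def stage_analyze(cfg: RunConfig, out: Path) -> list[Path]:
    traits_path = out / "traits.csv"
    if not traits_path.exists():
        raise InvalidArgumentError(f"{traits_path} does not exist; run the derive stage first")
    traits = pd.read_csv(traits_path)
    written: list[Path] = []

    summaries = []
    for response in cfg["stats"]["responses"]:
        if response in traits.columns:
            s = summarize(traits, response, ["phase", "treatment"])
            s.insert(0, "response", response)
            summaries.append(s)
    _write_csv(pd.concat(summaries, ignore_index=True), out / "summary.csv")
    written.append(out / "summary.csv")

    corr_vars = [
        c
        for c in ("FM", "DM", "MPPA", "V", "V_lemnatec", "V_keygene", "AGR_area")
        if c in traits.columns
    ]
    experimental = traits[traits["phase"].isin(["EP-1", "EP-2"])]
    cm = correlate(experimental, corr_vars)
    _write_csv(cm.r.reset_index(names="variable"), out / "correlations_r.csv")
    _write_csv(cm.p.reset_index(names="variable"), out / "correlations_p.csv")
    written += [out / "correlations_r.csv", out / "correlations_p.csv"]

    cell_tables, test_tables = [], []
    for response in cfg["stats"]["responses"]:
        if response not in traits.columns:
            continue
        for phase, res in fit_blues_by_phase(experimental, response).items():
            cells = res.cells.assign(response=response, phase=phase, method=res.method)
            tests = res.tests.assign(response=response, phase=phase)
            cell_tables.append(cells)
            test_tables.append(tests)
    _write_csv(pd.concat(cell_tables, ignore_index=True), out / "blues.csv")
    _write_csv(pd.concat(test_tables, ignore_index=True), out / "fixed_effect_tests.csv")
    written += [out / "blues.csv", out / "fixed_effect_tests.csv"]

    truth_path = out / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        gmult = np.asarray(truth["genotype_multipliers"])
        imult = np.asarray(truth["interaction_multipliers"])
        treatments = [float(t) for t in truth["treatments"]]
        blues = pd.concat(cell_tables, ignore_index=True)
        dm_blues = blues[(blues["response"] == "DM") & (blues["phase"] == "EP-1")]
        if not dm_blues.empty:
            report = recover_parameters(dm_blues, gmult, imult, treatments)
            rec_path = out / "recovery.json"
            rec_path.write_text(json.dumps(report, indent=1, sort_keys=True))
            written.append(rec_path)
    return written


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "derive": stage_derive,
    "analyze": stage_analyze,
}


def run_pipeline(
    cfg: RunConfig,
    out: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Execute the requested stages in order and write a run manifest.

    On a mid-run failure, partial outputs are preserved and the manifest
    records the failing stage before the exception propagates.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise InvalidArgumentError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": ordered,
        "config": cfg.raw,
        "outputs": {},
        "status": "running",
    }
    try:
        for stage in ordered:
            t0 = time.monotonic()
            log.info("stage %s starting", stage)
            paths = _STAGE_FUNCS[stage](cfg, out)
            manifest["outputs"][stage] = {
                str(p.relative_to(out)): _sha256(p) for p in paths
            }
            log.info("stage %s finished in %.1fs (%d artifacts)", stage, time.monotonic() - t0, len(paths))
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    manifest["status"] = "success"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
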