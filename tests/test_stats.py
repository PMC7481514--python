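"""Trial statistics: summaries, correlations, BLUEs, recovery."""

import numpy as np
import pandas as pd
import pytest

from ryenue.errors import InvalidArgumentError
from ryenue.stats import (
    correlate,
    fit_blues,
    recover_parameters,
    significance_stars,
    summarize,
)
from ryenue.synthetic import (
    HarvestModel,
    phase_end_areas,
    sample_growth_truth,
    simulate_harvests,
)
from ryenue.traits import NutrientSchedule, n_supplied


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_summary_moments_and_cv():
    df = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 4, "x": [1, 2, 3, 5, 5, 5, 5]})
    out = summarize(df, "x", ["g"]).set_index("g")
    assert out.loc["a", "mean"] == pytest.approx(2.0)
    assert out.loc["a", "sd"] == pytest.approx(1.0)
    assert out.loc["a", "cv"] == pytest.approx(0.5)
    assert out.loc["b", "sd"] == 0.0 and out.loc["b", "cv"] == 0.0
    assert (out["min"] <= out["mean"]).all() and (out["mean"] <= out["max"]).all()


def test_cv_of_nue_equals_cv_of_dm(full_harvests):
    """NUE = DM / Ns with Ns constant within a treatment x phase group, so
    the group CVs coincide to machine precision."""
    df = full_harvests[full_harvests.phase != "AP"].copy()
    ns = {t: n_supplied(NutrientSchedule(t)) for t in (0.5, 5.0)}
    df["NUE"] = df["DM"] / df["treatment"].map(ns)
    cv_dm = summarize(df, "DM", ["phase", "treatment"])["cv"].to_numpy()
    cv_nue = summarize(df, "NUE", ["phase", "treatment"])["cv"].to_numpy()
    np.testing.assert_allclose(cv_dm, cv_nue, rtol=1e-12)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def test_exact_linear_relations():
    x = np.arange(20.0)
    df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x})
    cm = correlate(df, ["x", "y", "z"])
    assert cm.r.loc["x", "y"] == pytest.approx(1.0)
    assert cm.r.loc["x", "z"] == pytest.approx(-1.0)
    np.testing.assert_allclose(cm.r.to_numpy(), cm.r.to_numpy().T)
    np.testing.assert_allclose(np.diag(cm.r.to_numpy()), 1.0)


def test_pairwise_complete_and_min_pairs():
    df = pd.DataFrame(
        {"a": [1.0, 2, 3, 4, np.nan], "b": [2.0, 4, 6, np.nan, 10], "c": [np.nan] * 3 + [1.0, 2.0]}
    )
    cm = correlate(df, ["a", "b", "c"])
    assert cm.n.loc["a", "b"] == 3
    assert np.isnan(cm.r.loc["a", "c"])  # only 1 complete pair


def test_significance_star_conventions():
    assert significance_stars(0.0001) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""


# ---------------------------------------------------------------------------
# mixed-model BLUEs
# ---------------------------------------------------------------------------

def test_balanced_blues_equal_cell_means(full_harvests):
    """On a balanced complete RCBD the REML cell estimates are exactly the
    arithmetic cell means, at any noise level."""
    df = full_harvests[full_harvests.phase == "EP-1"]
    res = fit_blues(df, "DM")
    assert res.method == "reml"
    cm = df.groupby(["genotype", "treatment"])["DM"].mean().sort_index().to_numpy()
    np.testing.assert_allclose(res.cells["estimate"], cm, atol=1e-8)
    assert (res.cells["se"] > 0).all()


def test_blues_track_cell_means_under_block_shifts(full_harvests):
    """Adding a constant to one replicate leaves the balanced-design
    identity intact: BLUEs still equal the (shifted) cell means, and
    genotype contrasts are unchanged."""
    df = full_harvests[full_harvests.phase == "EP-1"].copy()
    base = fit_blues(df, "DM")
    df.loc[df.replicate == 2, "DM"] += 5.0
    shifted = fit_blues(df, "DM")
    cm = df.groupby(["genotype", "treatment"])["DM"].mean().sort_index().to_numpy()
    np.testing.assert_allclose(shifted.cells["estimate"], cm, atol=1e-8)
    np.testing.assert_allclose(
        np.diff(shifted.cells["estimate"]), np.diff(base.cells["estimate"]), atol=1e-8
    )


def test_wald_test_degrees_of_freedom(full_harvests):
    res = fit_blues(full_harvests[full_harvests.phase == "EP-1"], "DM")
    df_by_term = dict(zip(res.tests["term"], res.tests["df"]))
    assert df_by_term == {"genotype": 75, "treatment": 1, "genotype:treatment": 75}
    assert (res.tests["pvalue"] < 0.001).all()


def test_single_replicate_falls_back_to_ols(full_harvests):
    df = full_harvests[(full_harvests.phase == "EP-1") & (full_harvests.replicate == 1)]
    res = fit_blues(df, "DM")
    assert res.method == "ols-fallback"
    cm = df.groupby(["genotype", "treatment"])["DM"].mean().sort_index().to_numpy()
    np.testing.assert_allclose(res.cells["estimate"], cm, atol=1e-8)


def test_missing_columns_raise(full_harvests):
    with pytest.raises(InvalidArgumentError):
        fit_blues(full_harvests.drop(columns=["replicate"]), "DM")


# ---------------------------------------------------------------------------
# recovery
# ---------------------------------------------------------------------------

def test_noise_free_recovery_is_perfect(full_design):
    truth = sample_growth_truth(seed=0, obs_noise_sd=0.0)
    harv = simulate_harvests(
        phase_end_areas(full_design, truth),
        truth,
        HarvestModel(fm_noise_sd=0.0, dm_noise_sd=0.0),
        seed=0,
    )
    res = fit_blues(harv[harv.phase == "EP-1"], "DM")
    rep = recover_parameters(
        res.cells, truth.genotype_multipliers,
        truth.interaction_multipliers, list(truth.treatments),
    )
    for entry in rep["per_treatment"].values():
        assert entry["spearman"] == pytest.approx(1.0)
        assert entry["top_decile_overlap"] == 1.0


def test_no_signal_gives_no_correlation(full_design):
    truth = sample_growth_truth(seed=0, genotype_sd=0.0, interaction_sd=0.0)
    harv = simulate_harvests(phase_end_areas(full_design, truth), truth, seed=0)
    res = fit_blues(harv[harv.phase == "EP-1"], "DM")
    rep = recover_parameters(res.cells, truth.genotype_multipliers)
    for entry in rep["per_treatment"].values():
        assert np.isnan(entry["pearson"])  # constant truth: undefined, flagged
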