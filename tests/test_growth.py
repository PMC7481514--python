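"""Logistic regrowth simulation: closed form, resets, treatment contrast."""

import numpy as np
import pytest

from ryenue.errors import InvalidArgumentError
from ryenue.synthetic import (
    GrowthTruth,
    generate_design,
    logistic_agr,
    logistic_area,
    logistic_rgr,
    sample_growth_truth,
    simulate_growth,
)


def constant_truth(K_low=80_000.0, K_high=160_000.0, n_genotypes=6, obs_sd=0.0):
    """Truth with all multipliers 1 and no block effects (deterministic)."""
    return GrowthTruth(
        K={0.5: K_low, 5.0: K_high},
        r=0.22,
        A0=6000.0,
        genotype_multipliers=np.ones(n_genotypes),
        interaction_multipliers=np.ones((n_genotypes, 2)),
        replicate_effects=np.zeros(4),
        treatments=(0.5, 5.0),
        obs_noise_sd=obs_sd,
    )


def test_noiseless_trajectory_equals_closed_form(small_design):
    truth = constant_truth()
    traj = simulate_growth(small_design.head(1), truth, seed=0)
    pot = small_design.iloc[0]
    for phase, grp in traj.groupby("phase"):
        K = truth.asymptote(pot.genotype, pot.treatment, phase)
        expected = logistic_area(grp["days_since_cut"].to_numpy(), K, truth.A0, truth.r)
        np.testing.assert_allclose(grp["area_side0"], expected, rtol=1e-12)
        np.testing.assert_allclose(grp["area_side90"], expected, rtol=1e-12)


def test_area_resets_to_A0_at_each_cut():
    truth = constant_truth()
    assert logistic_area(0.0, truth.K[5.0], truth.A0, truth.r) == pytest.approx(
        truth.A0, rel=1e-12
    )


def test_treatment_asymptote_ratio_reaches_two(full_design, full_truth):
    """With K(5 mM) = 2 K(0.5 mM), the mean final-area ratio between
    treatments in EP-1 approaches 2 (within Monte-Carlo sampling error)."""
    traj = simulate_growth(full_design, sample_growth_truth(seed=3), seed=3)
    ep1 = traj[traj.phase == "EP-1"]
    final = ep1[ep1.days_since_cut == ep1.days_since_cut.max()]
    ratio = (
        final[final.treatment == 5.0]["true_area"].mean()
        / final[final.treatment == 0.5]["true_area"].mean()
    )
    assert ratio == pytest.approx(2.0, rel=0.12)


def test_ap_equalization_removes_treatment_contrast(small_design):
    truth = constant_truth()
    traj = simulate_growth(small_design, truth, seed=0)
    ap = traj[traj.phase == "AP"]
    means = ap.groupby("treatment")["true_area"].mean()
    assert means[0.5] == pytest.approx(means[5.0], rel=1e-12)
    ep = traj[traj.phase == "EP-1"]
    means_ep = ep.groupby("treatment")["true_area"].mean()
    assert means_ep[5.0] > 1.2 * means_ep[0.5]


def test_analytic_agr_unimodal_and_rgr_decreasing():
    """dA/dt rises then falls (A0 < K/2) and d ln A/dt decays strictly."""
    t = np.linspace(0.1, 28, 200)
    agr = logistic_agr(t, 80_000, 6000, 0.22)
    rgr = logistic_rgr(t, 80_000, 6000, 0.22)
    peak = np.argmax(agr)
    assert 0 < peak < len(t) - 1
    assert np.all(np.diff(agr[:peak]) > 0)
    assert np.all(np.diff(agr[peak + 1 :]) < 0)
    assert np.all(np.diff(rgr) < 0)


def test_seed_determinism(small_design, full_truth):
    a = simulate_growth(small_design, full_truth, seed=5)
    b = simulate_growth(small_design, full_truth, seed=5)
    assert a.equals(b)


def test_invalid_cut_dates_raise(small_design):
    with pytest.raises(InvalidArgumentError):
        simulate_growth(small_design, constant_truth(), cut_dates=(28.0, 20.0, 84.0))
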