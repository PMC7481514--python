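"""Derived traits: MPPA, digital volumes, N supply, NUE, growth rates."""

import math

import numpy as np
import pandas as pd
import pytest

from ryenue.errors import InvalidArgumentError
from ryenue.traits import (
    NutrientSchedule,
    assign_phases,
    derive_trait_table,
    digital_volumes,
    growth_rates,
    mppa,
    n_supplied,
    nue,
)


def test_mppa_is_the_side_view_mean():
    assert mppa(1000, 2000) == 1500
    assert mppa(750, 750) == 750
    assert mppa(0, 0) == 0


@pytest.mark.parametrize(
    "areas, v, v_lt",
    [((1, 2, 3), 6, 6), ((2, 3, 4), 9, 24)],
)
def test_volume_sum_and_product(areas, v, v_lt):
    out = digital_volumes(*areas)
    assert out.V == v
    assert out.V_lemnatec == v_lt


def test_keygene_log_compresses_the_top_area():
    out = digital_volumes(100, 200, math.e**3)
    assert out.V_keygene == pytest.approx(309.0, abs=1e-9)
    alt = digital_volumes(100, 200, 1000.0, keygene_log="log10")
    assert alt.V_keygene == pytest.approx(309.0, abs=1e-9)
    with pytest.raises(InvalidArgumentError):
        digital_volumes(100, 200, 0.0)


def test_supplied_n_matches_the_protocol_doses():
    """7 x 100 ml applications of 0.5 / 5 mM N give 4.9 / 49 mg N per pot."""
    low = n_supplied(NutrientSchedule(concentration=0.5))
    mod = n_supplied(NutrientSchedule(concentration=5.0))
    assert low * 1000 == pytest.approx(4.9, abs=0.005)
    assert mod * 1000 == pytest.approx(49.0, abs=0.05)
    assert mod == pytest.approx(10 * low, rel=1e-12)
    with pytest.raises(InvalidArgumentError):
        n_supplied(NutrientSchedule(concentration=0.5, n_applications=0))


def test_nue_quotient_and_dose_inversion():
    assert nue(0.0, 0.0049) == 0.0
    assert nue(2.45, 0.049) == pytest.approx(50.0, rel=1e-12)
    assert nue(1.0, 0.01) == pytest.approx(10 * nue(1.0, 0.1), rel=1e-12)
    with pytest.raises(InvalidArgumentError):
        nue(1.0, 0.0)


def test_phase_assignment_half_open_intervals():
    cuts = (28.0, 56.0, 84.0)
    labels = assign_phases([0.0, 27.9, 28.0, 30.0, 56.0, 83.9, 84.0, 90.0], cuts)
    assert list(labels) == [
        "AP", "AP", "EP-1", "EP-1", "EP-2", "EP-2", "out-of-study", "out-of-study",
    ]
    with pytest.raises(InvalidArgumentError):
        assign_phases([1.0], (28.0, 20.0, 84.0))


def test_rgr_recovers_exponential_rate_exactly():
    """For an exact exponential series the phase RGR equals the generating
    rate to machine precision, whatever interior dates exist."""
    rate = 0.2
    for dates in ([0.0, 7.0], [0.0, 3.0, 7.0], [0.0, 1.0, 2.5, 6.0, 7.0]):
        t = np.asarray(dates)
        m = 100.0 * np.exp(rate * t)
        phase, intervals = growth_rates(t, m)
        assert phase["RGR"] == pytest.approx(rate, rel=1e-13)
        np.testing.assert_allclose(intervals["RGR"], rate, rtol=1e-12)


def test_agr_examples_and_constant_series():
    phase, _ = growth_rates([0.0, 7.0], [1000.0, 8000.0])
    assert phase["AGR_area"] == pytest.approx(1000.0)
    phase, intervals = growth_rates([0.0, 3.0, 7.0], [500.0, 500.0, 500.0])
    assert phase["AGR_area"] == 0.0
    assert phase["RGR"] == 0.0
    assert (intervals["AGR_area"] == 0).all()


def test_rgr_missing_when_endpoint_not_positive():
    phase, _ = growth_rates([0.0, 7.0], [0.0, 700.0])
    assert phase["AGR_area"] == pytest.approx(100.0)
    assert math.isnan(phase["RGR"])


def make_feature_table():
    rows = []
    for pot, trt in [("P1", 0.5), ("P2", 5.0)]:
        for t in (3.0, 27.0, 31.0, 55.0, 59.0, 83.0):
            base = 1000 + 100 * t + (500 if trt == 5.0 else 0)
            for view, a in [("side-0", base), ("side-90", base + 50), ("top", base / 2)]:
                rows.append(
                    {"pot_id": pot, "timestamp": t, "view": view, "area": a,
                     "empty_flag": False}
                )
    return pd.DataFrame(rows)


def make_harvests():
    rows = []
    for pot, g, trt in [("P1", 1, 0.5), ("P2", 2, 5.0)]:
        for phase in ("AP", "EP-1", "EP-2"):
            rows.append(
                {"pot_id": pot, "genotype": g, "treatment": trt, "replicate": 1,
                 "phase": phase, "phase_duration": 28.0, "FM": 6.0, "DM": 1.2}
            )
    return pd.DataFrame(rows)


def test_trait_table_end_to_end():
    schedules = {0.5: NutrientSchedule(0.5), 5.0: NutrientSchedule(5.0)}
    traits, intervals = derive_trait_table(
        make_feature_table(), make_harvests(), schedules
    )
    assert len(traits) == 6  # 2 pots x 3 phases
    ep1 = traits[(traits.pot_id == "P1") & (traits.phase == "EP-1")].iloc[0]
    # phase-end MPPA at t = 55: side areas 6500 / 6550
    assert ep1["MPPA"] == pytest.approx(6525.0)
    assert ep1["AGR_dm"] == pytest.approx(1.2 / 28.0)
    assert ep1["NUE"] == pytest.approx(1.2 / n_supplied(schedules[0.5]), rel=1e-12)
    ap = traits[(traits.pot_id == "P1") & (traits.phase == "AP")].iloc[0]
    assert math.isnan(ap["NUE"])  # NUE is defined for experimental phases only
    # per-interval table covers consecutive date pairs within phases
    p1_ep1 = intervals[(intervals.pot_id == "P1") & (intervals.phase == "EP-1")]
    assert len(p1_ep1) == 1
    assert set(intervals.phase) == {"AP", "EP-1", "EP-2"}


def test_empty_views_propagate_as_missing():
    feats = make_feature_table()
    feats.loc[
        (feats.pot_id == "P1") & (feats.timestamp == 55.0) & (feats.view == "top"),
        "empty_flag",
    ] = True
    schedules = {0.5: NutrientSchedule(0.5), 5.0: NutrientSchedule(5.0)}
    traits, _ = derive_trait_table(feats, make_harvests(), schedules)
    ep1 = traits[(traits.pot_id == "P1") & (traits.phase == "EP-1")].iloc[0]
    assert math.isnan(ep1["V"])          # volumes need all three views
    assert ep1["MPPA"] == pytest.approx(6525.0)  # sides unaffected
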