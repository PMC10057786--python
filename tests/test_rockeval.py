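"""Rock-Eval parameter assembly and the Sebag node/index machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from peatsense.rockeval import (NodeAreas, Pyrogram, TocFactors,
                                UndefinedIndexError, classify_depth_layer,
                                compute_parameters, i_index,
                                integrate_s2_nodes, r_index,
                                result_from_parameters)
from peatsense.synthetic_data import (ThermalComponent, default_composition,
                                      generate_pyrogram)

WINDOWS = [(200, 340), (340, 400), (400, 460), (460, np.inf)]


def cdf_oracle(centers, sigmas, fracs, lo=200.0, hi=650.0):
    """Closed-form node percentages for a truncated Gaussian mixture."""
    out = []
    for a, b in WINDOWS:
        mass = 0.0
        for c, s, f in zip(centers, sigmas, fracs):
            trunc = norm.cdf(hi, c, s) - norm.cdf(lo, c, s)
            mass += f * (norm.cdf(min(b, hi), c, s) - norm.cdf(max(a, lo), c, s)) / trunc
    # trailing-edge mass beyond 650 is excluded by truncation normalisation
        out.append(100.0 * mass)
    return np.array(out)


@pytest.mark.parametrize("fracs", [
    (1.0, 0.0, 0.0, 0.0),
    (0.25, 0.25, 0.25, 0.25),
    (0.1, 0.2, 0.3, 0.4),
])
def test_node_integration_matches_gaussian_cdf_oracle(fracs):
    p = generate_pyrogram(default_composition(fracs), total_s2=150.0, noise_sd=0.0)
    nodes = integrate_s2_nodes(p)
    got = np.array([nodes.A1, nodes.A2, nodes.A3, nodes.A4])
    want = cdf_oracle((310, 370, 430, 500), (15, 15, 15, 20), fracs)
    assert np.allclose(got, want, atol=1.0)  # within 1% absolute node area
    assert abs(got.sum() - 100.0) < 1e-6


def test_single_component_fills_its_window():
    p = generate_pyrogram(default_composition((1, 0, 0, 0)), total_s2=100.0)
    nodes = integrate_s2_nodes(p)
    assert nodes.A1 >= 97.5  # 340 degC lies 2 sigma above the 310 center


def test_uniform_signal_splits_by_window_length():
    temps = np.arange(200.0, 651.0)
    p = Pyrogram(pyrolysis_temps=temps, fid_signal=np.ones_like(temps))
    n = integrate_s2_nodes(p)
    # interval lengths 140 / 60 / 60 / 190 out of 450
    assert np.allclose([n.A1, n.A2, n.A3, n.A4],
                       np.array([140, 60, 60, 190]) / 450 * 100, atol=1e-9)


def test_zero_signal_raises_undefined():
    temps = np.arange(200.0, 651.0)
    p = Pyrogram(pyrolysis_temps=temps, fid_signal=np.zeros_like(temps))
    with pytest.raises(UndefinedIndexError):
        integrate_s2_nodes(p)


def test_short_ramp_rejected():
    temps = np.arange(200.0, 401.0)
    p = Pyrogram(pyrolysis_temps=temps, fid_signal=np.ones_like(temps))
    with pytest.raises(ValueError, match="460"):
        integrate_s2_nodes(p)


@pytest.mark.parametrize("areas, expected_r", [
    ((40, 0, 40, 20), 0.60),
    ((100, 0, 0, 0), 0.0),
    ((0, 0, 0, 100), 1.0),
])
def test_r_index_formula(areas, expected_r):
    a1, a2, a3, a4 = areas
    assert r_index(NodeAreas(a1, a2, a3, a4)) == pytest.approx(expected_r)


@pytest.mark.parametrize("areas, expected_i", [
    ((20, 20, 40, 20), 0.0),
    ((30, 30, 6, 34), 1.0),
    ((5, 5, 80, 10), np.log10(0.125)),
])
def test_i_index_formula(areas, expected_i):
    a1, a2, a3, a4 = areas
    assert i_index(NodeAreas(a1, a2, a3, a4)) == pytest.approx(expected_i)


def test_i_index_undefined_cases():
    with pytest.raises(UndefinedIndexError):
        i_index(NodeAreas(60, 40, 0, 0))
    with pytest.raises(UndefinedIndexError):
        i_index(NodeAreas(0, 0, 60, 40))


@given(
    a3_start=st.floats(5.0, 40.0),
    transfer=st.floats(0.5, 4.9),
)
@settings(max_examples=50, deadline=None)
def test_labile_to_refractory_transfer_monotonicity(a3_start, transfer):
    """Moving mass from A1/A2 to A3/A4 raises R and lowers I."""
    base = NodeAreas(50.0, 45.0 - a3_start, a3_start, 5.0)
    moved = NodeAreas(base.A1 - transfer, base.A2, base.A3 + transfer, base.A4)
    assert r_index(moved) > r_index(base)
    assert i_index(moved) < i_index(base)


def test_compute_parameters_hi_oi_and_tpk():
    comp = default_composition((0.3, 0.3, 0.25, 0.15))
    p = generate_pyrogram(comp, total_s2=200.0, s1=2.0, s3_co=30.0,
                          s3_co2=1200.0)
    res = compute_parameters(p)
    assert res.S2 == pytest.approx(200.0, rel=5e-3)
    assert res.S1 == pytest.approx(2.0, rel=1e-2)
    assert res.S3_CO == pytest.approx(30.0, rel=5e-3)
    assert res.HI == pytest.approx(100 * res.S2 / res.TOC)
    assert res.OI == pytest.approx(100 * res.S3_CO2 / res.TOC)
    # largest pool peaks at 310 or 370; argmax must land on a component center
    assert res.TpkS2 in (310.0, 370.0)
    assert res.TOC == pytest.approx(
        0.083 * (res.S1 + res.S2) + res.S3_CO * 12 / 280 + res.S3_CO2 * 12 / 440)


def test_hi_from_pre_integrated_row_matches_worked_example():
    """S2 = 40 mg HC/g at TOC = 10 wt% gives HI = 400 mg HC/g TOC."""
    row = {"S1": 1.0, "S2": 40.0, "S3_CO": 5.0, "S3_CO2": 50.0,
           "TOC": 10.0, "TpkS2": 410.0, "A1": 40.0, "A2": 20.0,
           "A3": 25.0, "A4": 15.0}
    res = result_from_parameters(row, "s")
    assert res.HI == pytest.approx(400.0)
    assert 300 <= res.HI <= 475  # the band typical of intact forest peat
    assert res.r_index == pytest.approx(0.40)


def test_zero_oxidation_gives_zero_oi():
    p = generate_pyrogram(default_composition((0.4, 0.3, 0.2, 0.1)),
                          total_s2=100.0, s1=1.0)
    res = compute_parameters(p)
    assert res.OI == 0.0


def test_parameters_stable_under_grid_refinement():
    from peatsense.synthetic_data import TempProgram

    comp = default_composition((0.3, 0.3, 0.25, 0.15))
    coarse = compute_parameters(generate_pyrogram(comp, 200.0, TempProgram(step_c=1.0)))
    fine = compute_parameters(generate_pyrogram(comp, 200.0, TempProgram(step_c=0.5)))
    assert abs(fine.S2 - coarse.S2) / coarse.S2 < 1e-3


def test_toc_zero_rejected():
    temps = np.arange(200.0, 651.0)
    p = Pyrogram(pyrolysis_temps=temps, fid_signal=np.zeros_like(temps))
    with pytest.raises(UndefinedIndexError):
        compute_parameters(p)


@pytest.mark.parametrize("top,bottom,expected", [
    (0, 10, "upper50"),
    (40, 50, "upper50"),
    (250, 260, "deep"),
    (60, 70, "below_water_table"),
    (40, 50.0, "upper50"),          # upper50 beats below_water_table
    (120, 130, "other"),
])
def test_depth_layer_classification(top, bottom, expected):
    assert classify_depth_layer(top, bottom, water_table_cm=40, clay_top_cm=300) == expected


def test_depth_layer_rejects_inverted_interval():
    with pytest.raises(ValueError):
        classify_depth_layer(50, 40, 40, 300)
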