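import numpy as np
import pytest

from peepsim.mechanics import (
    MechanicsError,
    PeepStepModel,
    brute_force_origin_slope,
    driving_ptp_via_peepstep,
    eelv_regression,
    peepstep_result,
    ptp_from_peepstep,
    pv_points,
    tidal_elastances,
    tidal_elastances_from,
)
from peepsim.model import simulate
from peepsim.params import make_default_config
from peepsim.protocols import isolated_lung_mode
from peepsim.spirometry import segment_breaths


# ---------------------------------------------------------------------------
# Worked example (two test lungs, VT 297 ml, PEEP step 8.4 cmH2O)
# ---------------------------------------------------------------------------

def test_worked_example_conventional_route():
    te = tidal_elastances_from(dpaw=14.1, dppl=5.3, vt=297.0)
    assert te.dptp == pytest.approx(8.8, abs=1e-12)
    assert te.el == pytest.approx((14.1 - 5.3) / 0.297, abs=1e-9)  # 29.6 cmH2O/L
    assert round(te.el, 1) == 29.6


def test_worked_example_peep_step_route():
    # (dPEEP/dEELV) x VT with the measured step of 8.4 cmH2O
    assert round(ptp_from_peepstep(8.4, 281.0, 297.0), 1) == 8.9
    res = peepstep_result(8.4, 281.0, 0.0)
    assert res.el_peepstep == pytest.approx(29.9, abs=0.05)
    assert res.dptp_ee == pytest.approx(8.4)


def test_peepstep_result_identities_and_inverse():
    for el in (15.0, 26.3, 52.6):
        deelv = 4.0 / el * 1000.0
        res = peepstep_result(4.0, deelv, 0.0)
        assert res.el_peepstep == pytest.approx(el, rel=1e-12)
    res = peepstep_result(8.0, 300.0, 0.5)
    assert res.dptp_ee == pytest.approx(8.0 - 0.5, abs=1e-15)
    assert res.ecw_ee == pytest.approx(0.5 / 0.3, rel=1e-12)
    with pytest.raises(MechanicsError):
        peepstep_result(8.0, 0.0, 0.0)


def test_elastance_identity_holds_on_simulated_breaths(steady_zeep_run):
    for b in segment_breaths(steady_zeep_run)[8:]:
        te = tidal_elastances(b)
        assert te.etot == pytest.approx(te.ecw + te.el, abs=1e-12)
    with pytest.raises(MechanicsError):
        tidal_elastances_from(10.0, 5.0, 0.0)


def test_isolated_lung_tidal_el_equals_etot():
    te = tidal_elastances_from(dpaw=12.0, dppl=0.0, vt=300.0)
    assert te.el == te.etot


def test_tidal_chest_wall_elastance_of_the_calibrated_arm(steady_zeep_run):
    late = segment_breaths(steady_zeep_run)[10:]
    ecw = np.mean([tidal_elastances(b).ecw for b in late])
    assert ecw == pytest.approx(18.0, abs=1.0)


def test_driving_pressure_reduces_to_dpaw_without_chest_wall():
    assert driving_ptp_via_peepstep(12.3, 0.0, 300.0) == pytest.approx(12.3)
    assert driving_ptp_via_peepstep(14.1, 18.0, 297.0) == pytest.approx(14.1 - 5.346)


def test_peepstep_and_tidal_routes_differ_by_exactly_the_static_term(step_run_0_8_0):
    # the PEEP-step elastance contains the (small) end-expiratory chest-wall
    # elastance, so the two driving-pressure routes differ by ECW_EE x VT
    results = PeepStepModel(step_run_0_8_0, arm="2L/normal").fit()
    s = results.steps[0]
    ptp_tidal = s.el_tidal * s.vt / 1000.0
    ptp_step = ptp_from_peepstep(s.dpeep, s.deelv, s.vt)
    gap = ptp_step - ptp_tidal
    assert gap == pytest.approx(s.ecw_ee * s.vt / 1000.0, abs=0.1)
    assert gap < 0.6


# ---------------------------------------------------------------------------
# P/V points
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def staircase_run():
    cfg = make_default_config(2, "normal")
    return cfg, simulate(cfg, [(0.0, 25), (4.0, 25), (8.0, 25), (12.0, 25)])


def test_pv_line_slope_recovers_the_peep_inflation_elastance(staircase_run):
    cfg, wf = staircase_run
    pts = pv_points(wf)
    expected = cfg.lung.elastance + cfg.abdomen.static_elastance
    assert pts.slope == pytest.approx(expected, rel=0.05)


def test_end_inspiratory_points_sit_right_of_the_lung_line_by_dppl(staircase_run):
    cfg, wf = staircase_run
    breaths = segment_breaths(wf)
    b = breaths[40]  # settled breath at PEEP 4
    te = tidal_elastances(b)
    shift = (b.paw_ei - b.paw_ee) - (te.el * b.vti / 1000.0)
    assert shift == pytest.approx(b.ppl_ei - b.ppl_ee, abs=0.05)


def test_isolated_lung_airway_and_transpulmonary_points_coincide():
    cfg = isolated_lung_mode(make_default_config(2, "normal"))
    wf = simulate(cfg, [(5.0, 22), (9.0, 22)])
    pts = pv_points(wf)
    assert np.allclose(pts.paw_ee, pts.ptp_ee)
    assert np.allclose(pts.paw_ei, pts.ptp_ei)


def test_isolated_lung_line_aligns_with_attached_end_expiratory_points(staircase_run):
    # the attached model's end-expiratory airway P/V points lie on the
    # isolated-lung line (slope 1/C_L) after fitting the parallel offset
    cfg, wf = staircase_run
    pts = pv_points(wf)
    # fit only the settled end-expiratory points (last breaths of each level)
    idx = [24, 49, 74, 99]
    v = pts.eelv[idx]
    p = pts.paw_ee[idx]
    pred = v / cfg.lung.total_compliance
    offset = np.mean(p - pred)
    assert np.max(np.abs(p - pred - offset)) < 0.5


def test_single_level_pv_fit_raises():
    cfg = make_default_config(2, "normal")
    wf = simulate(cfg, [(0.0, 5)])
    with pytest.raises(MechanicsError):
        pv_points(wf)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def test_perfect_pairs_regress_to_unit_slope():
    x = np.array([80.0, 160.0, 300.0, 440.0, 620.0])
    reg = eelv_regression(x, x)
    assert reg.slope == pytest.approx(1.0, abs=1e-12)
    assert reg.r2 == pytest.approx(1.0, abs=1e-12)


def test_closed_form_slope_matches_brute_force_grid():
    rng = np.random.default_rng(5)
    x = rng.uniform(50, 600, 12)
    y = 0.95 * x + rng.normal(0, 4, 12)
    reg = eelv_regression(y, x)
    assert reg.slope == pytest.approx(brute_force_origin_slope(y, x), abs=1e-6)


def test_regression_error_cases():
    with pytest.raises(MechanicsError):
        eelv_regression(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
    with pytest.raises(MechanicsError):
        eelv_regression(np.zeros(5), np.zeros(5))


def test_summary_reports_the_fit(step_run_0_8_0):
    results = PeepStepModel(step_run_0_8_0, arm="2L/normal").fit()
    text = results.summary()
    assert "2L/normal" in text
    assert "dPEEP" in text
    frame = results.to_frame()
    assert set(["dpeep", "deelv", "el_peepstep", "deelv_truth"]) <= set(frame.columns)
    assert len(frame) == 2  # one up, one down step
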