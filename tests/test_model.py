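import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peepsim.model import (
    CalibrationError,
    CapacityError,
    ModelState,
    VentilatorDrive,
    calibrate_chest_wall,
    derivatives,
    equilibrium_linearized,
    equilibrium_solver,
    hydraulic_head,
    initial_state_at_frc,
    measure_tidal_ecw,
    pleural_gas_amount,
    pleural_pressure_of,
    simulate,
    simulate_cpap,
    step,
    water_levels,
)
from peepsim.params import make_default_config
from peepsim.spirometry import segment_breaths


# ---------------------------------------------------------------------------
# Baseline / statics
# ---------------------------------------------------------------------------

def test_frc_baseline_is_set_by_the_evacuated_pleura():
    cfg = make_default_config(1, "normal")
    state = initial_state_at_frc(cfg)
    # transpulmonary pressure 0 - (-5) = 5 cmH2O inflates 19 ml/cmH2O to 95 ml
    assert state.pleural_pressure == pytest.approx(-5.0)
    assert state.airway_pressure == pytest.approx(0.0)
    assert state.lung_volume == pytest.approx(95.0)
    assert state.displaced_water == 0.0
    # the hydrostatic head exactly balances the pleural vacuum at the valve
    assert hydraulic_head(cfg, 0.0) == pytest.approx(5.0)


def test_zero_evacuation_leaves_the_lung_at_residual_volume():
    cfg = make_default_config(1, "normal")
    cfg = cfg.replace(
        chest_wall=cfg.chest_wall.__class__(
            wall_compliance=cfg.chest_wall.wall_compliance, evacuation_pressure=0.0
        )
    )
    state = initial_state_at_frc(cfg)
    assert state.lung_volume == pytest.approx(0.0)
    assert state.pleural_pressure == pytest.approx(0.0)
    assert hydraulic_head(cfg, 0.0) == pytest.approx(0.0)


def test_displaced_water_lowers_the_head_by_the_surface_geometry():
    cfg = make_default_config(2, "normal")
    geometric_only = cfg.replace(
        abdomen=cfg.abdomen.__class__(residual_static_elastance=0.0)
    )
    drop = hydraulic_head(geometric_only, 0.0) - hydraulic_head(geometric_only, 1000.0)
    assert drop == pytest.approx(1000 * (1 / 1500 + 1 / 1800), abs=1e-9)  # 1.22


def test_water_bookkeeping_identity():
    cfg = make_default_config(2, "normal")
    drop, rise = water_levels(cfg, 900.0)
    assert drop * cfg.abdomen.container_area == pytest.approx(900.0)
    assert rise * cfg.abdomen.sack_area == pytest.approx(900.0)


def test_sudden_inflation_with_frozen_valve_raises_pleural_pressure_by_gas_and_wall():
    # closed-form limit: no water flow, pleural rise = dV / (C_wall + C_gas)
    cfg = make_default_config(2, "normal")
    state = initial_state_at_frc(cfg)
    p0 = state.pleural_pressure
    dv = 100.0
    p1 = pleural_pressure_of(cfg, state.lung_volume + dv, 0.0)
    c_gas = cfg.chest_wall.pleural_gas_volume / (
        cfg.chest_wall.atmospheric_pressure + p0
    )
    expected = dv / (cfg.chest_wall.wall_compliance + c_gas)
    assert p1 - p0 == pytest.approx(expected, rel=0.02)


# ---------------------------------------------------------------------------
# Equilibrium solver (closed-form statics oracle)
# ---------------------------------------------------------------------------

def test_equilibrium_at_zeep_is_the_baseline():
    cfg = make_default_config(2, "normal")
    eq = equilibrium_solver(cfg, 0.0)
    assert eq.delta_eelv == pytest.approx(0.0, abs=1e-9)
    assert eq.pleural_pressure == pytest.approx(-5.0, abs=1e-9)


def test_equilibrium_matches_hand_arithmetic_for_two_lungs():
    # E_L = 26.3 cmH2O/L, E_cw,stat ~ 1.5 -> dEELV ~ 8.4/27.8 L ~ 302 ml
    cfg = make_default_config(2, "normal")
    eq = equilibrium_solver(cfg, 8.4)
    assert eq.delta_eelv == pytest.approx(8.4 / 27.8 * 1000, abs=3.0)
    assert eq.transpulmonary_pressure == pytest.approx(8.4 - eq.pleural_pressure, abs=1e-12)


def test_linearized_form_tracks_the_exact_solve():
    cfg = make_default_config(3, "stiff")
    exact = equilibrium_solver(cfg, 12.0)
    lin = equilibrium_linearized(cfg, 12.0)
    assert lin.delta_eelv == pytest.approx(exact.delta_eelv, rel=0.01)
    # the linearisation overstates the pleural rise by the gas/wall softening
    assert lin.pleural_pressure >= exact.pleural_pressure
    assert lin.pleural_pressure - exact.pleural_pressure < 0.15


def test_mean_transmission_at_the_largest_step_matches_the_bench():
    # pooled end-expiratory dPTP for dPEEP 12.2 over two- and three-lung arms
    vals = []
    for n in (2, 3):
        for mode in ("normal", "stiff"):
            eq = equilibrium_solver(make_default_config(n, mode), 12.2)
            vals.append(eq.transpulmonary_pressure - 5.0)
    assert np.mean(vals) == pytest.approx(11.4, abs=0.2)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    peep=st.floats(0.0, 12.0),
    higher=st.floats(0.1, 6.0),
    n=st.integers(2, 3),
)
def test_equilibrium_monotonicity_and_bounded_transmission(peep, higher, n):
    cfg = make_default_config(n, "normal")
    lo = equilibrium_solver(cfg, peep)
    hi = equilibrium_solver(cfg, peep + higher)
    assert hi.delta_eelv > lo.delta_eelv  # strictly increasing in PEEP
    dptp = hi.transpulmonary_pressure - lo.transpulmonary_pressure
    assert 0.0 < dptp <= higher + 1e-9  # dPTP_EE never exceeds dPEEP


def test_equilibrium_above_capacity_raises():
    cfg = make_default_config(1, "normal")
    with pytest.raises(CapacityError):
        equilibrium_solver(cfg, 35.0)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def test_derivatives_vanish_at_equilibrium():
    cfg = make_default_config(2, "normal")
    eq = equilibrium_solver(cfg, 6.0)
    state = ModelState(0.0, eq.lung_volume, eq.displaced_water, 0.0, 0.0)
    dv, dw = derivatives(state, cfg, VentilatorDrive(phase="pause", peep=6.0))
    assert dv == 0.0
    assert abs(dw) < 1e-9


def test_step_is_a_fixed_point_at_equilibrium():
    cfg = make_default_config(2, "normal")
    eq = equilibrium_solver(cfg, 6.0)
    state = ModelState(0.0, eq.lung_volume, eq.displaced_water, 0.0, 0.0)
    drive = VentilatorDrive(phase="pause", peep=6.0)
    out = state
    for _ in range(10):
        out = step(out, cfg, cfg.integrator_dt, drive)
    assert out.lung_volume == pytest.approx(state.lung_volume, abs=1e-9)
    assert out.displaced_water == pytest.approx(state.displaced_water, abs=1e-9)


def test_step_conserves_the_pleural_gas_amount():
    cfg = make_default_config(2, "normal")
    state = initial_state_at_frc(cfg)
    state.airway_pressure = 0.0
    n_ref = pleural_gas_amount(cfg, state)
    drive = VentilatorDrive(phase="inspiration", prescribed_flow=320.0, peep=0.0)
    for _ in range(300):  # 0.3 s of inflation
        state = step(state, cfg, cfg.integrator_dt, drive)
        assert pleural_gas_amount(cfg, state) == pytest.approx(n_ref, rel=1e-9)


def test_step_raises_capacity_error_before_overfilling():
    cfg = make_default_config(1, "normal")
    state = initial_state_at_frc(cfg)
    drive = VentilatorDrive(phase="inspiration", prescribed_flow=400.0, peep=0.0)
    with pytest.raises(CapacityError):
        for _ in range(2000):
            state = step(state, cfg, cfg.integrator_dt, drive)


@pytest.mark.parametrize("n,mode", [(2, "normal"), (3, "stiff")])
@pytest.mark.parametrize("peep", [0.0, 4.0, 8.0, 12.0])
def test_cpap_long_run_converges_to_the_static_oracle(n, mode, peep):
    cfg = make_default_config(n, mode)
    eq = equilibrium_solver(cfg, peep)
    end = simulate_cpap(cfg, peep, 120.0)
    assert end.lung_volume == pytest.approx(eq.lung_volume, abs=1.0)
    assert end.pleural_pressure == pytest.approx(eq.pleural_pressure, abs=0.05)


def test_ventilated_peep_step_delta_matches_the_oracle(step_run_0_8_0, two_lung_config):
    wf = step_run_0_8_0
    spb = wf.samples_per_breath
    v_base = wf.vlung[25 * spb - 10 : 25 * spb].mean()
    v_high = wf.vlung[50 * spb - 10 : 50 * spb].mean()
    p_base = wf.ppl[25 * spb - 10 : 25 * spb].mean()
    p_high = wf.ppl[50 * spb - 10 : 50 * spb].mean()
    eq = equilibrium_solver(two_lung_config, 8.4)
    assert v_high - v_base == pytest.approx(eq.delta_eelv, rel=0.01)
    assert p_high - p_base == pytest.approx(eq.pleural_pressure + 5.0, abs=0.1)


def test_post_step_pleural_transient_rises_then_decays_monotonically(step_run_0_8_0):
    wf = step_run_0_8_0
    spb = wf.samples_per_breath
    ppl_ee = np.array(
        [wf.ppl[(k + 1) * spb - 10 : (k + 1) * spb].mean() for k in range(75)]
    )
    baseline = ppl_ee[24]
    transient = ppl_ee[25:50]
    final = transient[-1]
    assert transient[0] > final  # first end-expiration overshoots the new equilibrium
    assert np.all(np.diff(transient) < 1e-6)  # then monotone decay
    assert final > baseline  # small residual rise (static chest-wall elastance)
    assert final - baseline < 0.6


def test_peep_up_down_returns_to_baseline(step_run_0_8_0):
    wf = step_run_0_8_0
    spb = wf.samples_per_breath
    v0 = wf.vlung[25 * spb - 10 : 25 * spb].mean()
    v1 = wf.vlung[75 * spb - 10 : 75 * spb].mean()
    p0 = wf.ppl[25 * spb - 10 : 25 * spb].mean()
    p1 = wf.ppl[75 * spb - 10 : 75 * spb].mean()
    assert abs(v1 - v0) < 2.0
    assert abs(p1 - p0) < 0.1


def test_gas_amount_is_conserved_across_a_full_protocol(step_run_0_8_0, two_lung_config):
    # the recorded pleural pressure and lung volume must be consistent with a
    # constant gas amount given the water displacement implied by them
    wf = step_run_0_8_0
    cfg = two_lung_config
    cw = cfg.chest_wall
    k_w = cfg.abdomen.static_elastance / 1000.0
    # invert the pleural solve sample-by-sample for the implied water, then
    # check the head/hydrostatic relation stays within the valve's dynamics
    p0 = cw.evacuation_pressure
    v0 = cfg.lung.total_compliance * (0.0 - p0)
    n0 = (cw.atmospheric_pressure + p0) * cw.pleural_gas_volume
    v_gas = n0 / (cw.atmospheric_pressure + wf.ppl)
    w = v_gas - cw.pleural_gas_volume + (wf.vlung - v0) - cw.wall_compliance * (wf.ppl - p0)
    # the implied water displacement is smooth and bounded by the step size
    assert np.all(np.isfinite(w))
    assert abs(w[0]) < 5.0
    assert np.max(np.abs(np.diff(w))) < 2.0  # < 200 ml/s through the valve


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def test_default_configs_hit_the_tidal_chest_wall_targets():
    assert measure_tidal_ecw(make_default_config(2, "normal")) == pytest.approx(18.0, abs=0.2)
    assert measure_tidal_ecw(make_default_config(2, "stiff")) == pytest.approx(24.0, abs=0.2)


def test_calibration_is_a_fixed_point_at_the_current_value():
    cfg = make_default_config(2, "normal")
    out = calibrate_chest_wall(cfg, 18.0, tol=0.2)
    assert out.chest_wall.wall_compliance == pytest.approx(
        cfg.chest_wall.wall_compliance, abs=0.5
    )


def test_calibration_reaches_a_new_target():
    cfg = make_default_config(2, "normal")
    out = calibrate_chest_wall(cfg, 21.0, tol=0.2)
    assert measure_tidal_ecw(out) == pytest.approx(21.0, abs=0.2)


def test_unattainable_calibration_target_raises():
    cfg = make_default_config(2, "normal")
    with pytest.raises(CalibrationError):
        calibrate_chest_wall(cfg, 1.0)  # below the static chest-wall elastance
    with pytest.raises(CalibrationError):
        calibrate_chest_wall(cfg, 500.0)


def test_simulation_is_deterministic(two_lung_config):
    a = simulate(two_lung_config, [(0.0, 2), (6.0, 2)])
    b = simulate(two_lung_config, [(0.0, 2), (6.0, 2)])
    assert np.array_equal(a.paw, b.paw)
    assert np.array_equal(a.vlung, b.vlung)


def test_breaths_segment_cleanly_from_the_simulator(steady_zeep_run):
    assert len(segment_breaths(steady_zeep_run)) == 15
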