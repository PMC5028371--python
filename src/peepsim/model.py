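"""Lumped-parameter dynamics of the lung / pleural space / hydraulic abdomen.

Governing equations (quasi-static linear lung behind a small airway
resistance, isothermal ideal-gas pleural space, linear wall bulging, linear
resistive valve, perfectly plastic abdominal sack):

* lung volume above residual ``V`` obeys ``V = C_L * P_TP`` with
  ``P_TP = P_alv - P_PL``; airway flow is prescribed during inspiration and
  passive through the PEEP valve during expiration;
* displaced water ``w`` (container -> sack) obeys
  ``dw/dt = (P_PL + head(w)) / R_valve`` with
  ``head(w) = -P_evac - w * E_stat/1000`` where ``E_stat`` is the static
  chest-wall elastance (hydrostatic geometry plus a small calibrated
  residual term);
* pleural pressure follows from conservation of the pleural gas amount
  ``(P_atm + P_PL) * V_gas`` with
  ``V_gas = V_gas0 - dV_lung + w + C_wall * (P_PL - P_evac)``,
  solved algebraically each step (a quadratic), so the gas amount is
  conserved to machine precision by construction.

Integration is a fixed-step classical 4th-order Runge-Kutta at 1 ms with
breath-phase boundaries aligned to the step grid; recorded channels are
emitted at 100 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import ModelConfig
from .ventilator import EXPIRATION, INSPIRATION, PAUSE, cycle_timing
from .waveforms import PeepTransition, Waveforms


class IntegrationError(RuntimeError):
    """The state left its physical bounds during integration."""


class CapacityError(IntegrationError):
    """Lung volume would exceed the test-lung capacity ceiling."""


class CalibrationError(RuntimeError):
    """Chest-wall calibration target unattainable within the bracket."""


@dataclass
class ModelState:
    """Instantaneous dynamical state of the bench model."""

    time: float
    lung_volume: float  # ml above residual
    displaced_water: float  # ml moved container -> sack from baseline
    pleural_pressure: float  # cmH2O gauge
    airway_pressure: float  # cmH2O gauge
    ventilator_phase: str = "expiration"


@dataclass(frozen=True)
class VentilatorDrive:
    """External drive seen by the model at one instant."""

    phase: str = "expiration"
    prescribed_flow: float = 0.0  # ml/s, inspiratory positive
    peep: float = 0.0


@dataclass(frozen=True)
class EquilibriumResult:
    """Static end-expiratory equilibrium at a given PEEP."""

    peep: float
    delta_eelv: float  # ml above the ZEEP equilibrium
    lung_volume: float  # ml above residual
    pleural_pressure: float  # cmH2O
    transpulmonary_pressure: float  # cmH2O
    displaced_water: float  # ml


def _pleural_coeffs(config: ModelConfig) -> tuple[float, float, float, float, float]:
    """Constants of the algebraic pleural-pressure solve."""
    cw = config.chest_wall
    p0 = cw.evacuation_pressure
    c_l = config.lung.total_compliance
    v0 = c_l * (0.0 - p0)  # lung volume above residual at baseline FRC
    n0 = (cw.atmospheric_pressure + p0) * cw.pleural_gas_volume
    return p0, v0, n0, cw.wall_compliance, cw.atmospheric_pressure


def pleural_pressure_of(config: ModelConfig, lung_volume: float, displaced_water: float) -> float:
    """Pleural pressure from gas-amount conservation (exact, closed form)."""
    if config.isolated_lung:
        return 0.0
    p0, v0, n0, c_wall, p_atm = _pleural_coeffs(config)
    g = (
        config.chest_wall.pleural_gas_volume
        - (lung_volume - v0)
        + displaced_water
        - c_wall * p0
    )
    if c_wall == 0.0:
        return n0 / g - p_atm
    b = g + c_wall * p_atm
    c = p_atm * g - n0
    disc = b * b - 4.0 * c_wall * c
    # root of smaller magnitude (the physical gauge pressure)
    return 2.0 * c / (-b - math.sqrt(disc))


def hydraulic_head(config: ModelConfig, displaced_water: float) -> float:
    """Hydrostatic driving head (cmH2O) at the valve for a given displacement.

    At baseline the head exactly balances the evacuated pleural pressure;
    each ml moved from container to sack lowers it by the static chest-wall
    elastance per ml.
    """
    ab = config.abdomen
    return -config.chest_wall.evacuation_pressure - displaced_water * ab.static_elastance / 1000.0


def initial_state_at_frc(config: ModelConfig) -> ModelState:
    """Static baseline: pleural space evacuated, airway open to atmosphere.

    Pleural pressure equals the evacuation target (default -5 cmH2O), so the
    lung sits at the volume given by a transpulmonary pressure of +5 cmH2O
    and the container water level exceeds the sack level by exactly the head
    that balances the pleural vacuum at the valve.
    """
    p0 = config.chest_wall.evacuation_pressure
    if config.isolated_lung:
        p0 = 0.0
    v0 = config.lung.total_compliance * (0.0 - p0)
    return ModelState(
        time=0.0,
        lung_volume=v0,
        displaced_water=0.0,
        pleural_pressure=p0,
        airway_pressure=0.0,
        ventilator_phase="expiration",
    )


def water_levels(config: ModelConfig, displaced_water: float) -> tuple[float, float]:
    """Container level drop and sack level rise (cm) for a displacement."""
    ab = config.abdomen
    return displaced_water / ab.container_area, displaced_water / ab.sack_area


def pleural_gas_amount(config: ModelConfig, state: ModelState) -> float:
    """Conserved quantity (absolute pressure x gas volume) of the pleura."""
    p0, v0, _, c_wall, p_atm = _pleural_coeffs(config)
    v_gas = (
        config.chest_wall.pleural_gas_volume
        - (state.lung_volume - v0)
        + state.displaced_water
        + c_wall * (state.pleural_pressure - p0)
    )
    return (p_atm + state.pleural_pressure) * v_gas


# ---------------------------------------------------------------------------
# Public single-step interface
# ---------------------------------------------------------------------------

def derivatives(
    state: ModelState, config: ModelConfig, drive: VentilatorDrive
) -> tuple[float, float]:
    """Time-derivatives (dV_lung/dt, d_water/dt) in ml/s.

    Raises :class:`IntegrationError` if the state is outside its physical
    bounds, naming the violated invariant.
    """
    lung = config.lung
    if state.lung_volume < lung.residual_volume - 1e-9:
        raise IntegrationError("lung_volume below residual volume")
    if state.lung_volume > lung.total_capacity + 1e-9:
        raise CapacityError("lung_volume above total capacity")
    p_pl = pleural_pressure_of(config, state.lung_volume, state.displaced_water)
    if drive.phase == "inspiration":
        dv = drive.prescribed_flow
    elif drive.phase == "pause":
        dv = 0.0
    else:
        p_alv = state.lung_volume / lung.total_compliance + p_pl
        r_total = lung.airway_resistance + config.ventilator.expiratory_resistance
        dv = -max(0.0, p_alv - drive.peep) / r_total
    if config.isolated_lung:
        return dv, 0.0
    dw = (p_pl + hydraulic_head(config, state.displaced_water)) / config.abdomen.valve_resistance
    return dv, dw


def step(
    state: ModelState,
    config: ModelConfig,
    dt: float,
    drive: VentilatorDrive | None = None,
) -> ModelState:
    """Advance the state by one fixed RK4 step of length ``dt``."""
    if dt > config.integrator_dt + 1e-12:
        raise ValueError("dt must not exceed the configured integrator_dt")
    drive = drive or VentilatorDrive(peep=config.ventilator.peep)

    def f(v: float, w: float) -> tuple[float, float]:
        probe = ModelState(state.time, v, w, 0.0, 0.0, drive.phase)
        return derivatives(probe, config, drive)

    v, w = state.lung_volume, state.displaced_water
    k1v, k1w = f(v, w)
    k2v, k2w = f(v + 0.5 * dt * k1v, w + 0.5 * dt * k1w)
    k3v, k3w = f(v + 0.5 * dt * k2v, w + 0.5 * dt * k2w)
    k4v, k4w = f(v + dt * k3v, w + dt * k3w)
    v_new = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    w_new = w + dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
    if v_new > config.lung.total_capacity:
        raise CapacityError(
            f"lung volume {v_new:.1f} ml exceeds capacity "
            f"{config.lung.total_capacity:.0f} ml"
        )
    p_pl = pleural_pressure_of(config, v_new, w_new)
    p_alv = v_new / config.lung.total_compliance + p_pl
    return ModelState(
        time=state.time + dt,
        lung_volume=v_new,
        displaced_water=w_new,
        pleural_pressure=p_pl,
        airway_pressure=p_alv,
        ventilator_phase=drive.phase,
    )


# ---------------------------------------------------------------------------
# Static equilibrium oracle
# ---------------------------------------------------------------------------

def equilibrium_solver(config: ModelConfig, peep: float) -> EquilibriumResult:
    """Exact static end-expiratory equilibrium at a given PEEP.

    Solves the coupled statics (linear lung, gas law, hydrostatic spring)
    for zero valve flow and zero airway flow.  ΔEELV is referenced to the
    ZEEP equilibrium (the evacuated baseline).  Raises
    :class:`CapacityError` if the equilibrium lung volume exceeds capacity.
    """
    if peep < 0:
        raise ValueError("peep must be >= 0")
    lung = config.lung
    c_l = lung.total_compliance
    if config.isolated_lung:
        v = c_l * peep
        if v > lung.total_capacity:
            raise CapacityError("equilibrium lung volume above capacity")
        return EquilibriumResult(peep, v, v, 0.0, peep, 0.0)
    p0, v0, n0, c_wall, p_atm = _pleural_coeffs(config)
    k_w = config.abdomen.static_elastance / 1000.0  # cmH2O per ml

    def residual(w: float) -> float:
        p_pl = p0 + k_w * w
        v = c_l * (peep - p_pl)
        v_gas = config.chest_wall.pleural_gas_volume - (v - v0) + w + c_wall * (p_pl - p0)
        return (p_atm + p_pl) * v_gas - n0

    if peep == 0.0:
        w = 0.0
    else:
        w = brentq(residual, -5.0e4, 5.0e4, xtol=1e-10)
    p_pl = p0 + k_w * w
    v = c_l * (peep - p_pl)
    if v > lung.total_capacity:
        raise CapacityError("equilibrium lung volume above capacity")
    return EquilibriumResult(
        peep=peep,
        delta_eelv=v - v0,
        lung_volume=v,
        pleural_pressure=p_pl,
        transpulmonary_pressure=peep - p_pl,
        displaced_water=w,
    )


def equilibrium_linearized(config: ModelConfig, peep: float) -> EquilibriumResult:
    """Small-signal closed form: ΔEELV = ΔPEEP / (E_L + E_cw,stat).

    The linearisation treats all displaced volume as water (ignoring the
    softening by pleural-gas compressibility and wall bulging), so it
    slightly overstates the end-expiratory pleural rise; the exact solve
    above is the oracle used in tests.
    """
    e_l = config.lung.elastance
    e_stat = 0.0 if config.isolated_lung else config.abdomen.static_elastance
    p0 = 0.0 if config.isolated_lung else config.chest_wall.evacuation_pressure
    delta = peep / (e_l + e_stat) * 1000.0
    p_pl = p0 + e_stat * delta / 1000.0
    v0 = config.lung.total_compliance * (0.0 - p0)
    return EquilibriumResult(
        peep=peep,
        delta_eelv=delta,
        lung_volume=v0 + delta,
        pleural_pressure=p_pl,
        transpulmonary_pressure=peep - p_pl,
        displaced_water=delta,
    )


# ---------------------------------------------------------------------------
# Fast breath-by-breath simulation
# ---------------------------------------------------------------------------

def simulate(
    config: ModelConfig,
    peep_schedule: list[tuple[float, int]],
    initial: ModelState | None = None,
) -> Waveforms:
    """Ventilate the model through a schedule of (PEEP, n_breaths) levels.

    PEEP changes take effect at a breath boundary (the ventilator commands
    the expiratory valve for the coming breath), exactly as on the bench.
    Returns the 100-Hz waveform record with PEEP transitions annotated.
    Raises :class:`CapacityError` if the lung is driven above capacity.
    """
    vent = config.ventilator
    timing = cycle_timing(vent)
    dt = config.integrator_dt
    n_sub = round(1.0 / (config.record_rate * dt))
    spb = round(timing.cycle_time * config.record_rate)  # samples per breath
    sub_pb = spb * n_sub
    flow_end = round(timing.flow_time / dt)
    pause_end = round((timing.flow_time + timing.pause_time) / dt)

    # phase code per substep of one cycle
    phase_sub = np.empty(sub_pb, dtype=np.int8)
    phase_sub[:flow_end] = INSPIRATION
    phase_sub[flow_end:pause_end] = PAUSE
    phase_sub[pause_end:] = EXPIRATION
    phase_sub_l = phase_sub.tolist()
    phase_rec = phase_sub[::n_sub].copy()

    lung = config.lung
    c_l = lung.total_compliance
    inv_cl = 1.0 / c_l
    capacity = lung.total_capacity
    r_total = lung.airway_resistance + vent.expiratory_resistance
    inv_rt = 1.0 / r_total
    r_exp_frac = vent.expiratory_resistance * inv_rt
    q_insp = timing.inspiratory_flow
    r_aw = lung.airway_resistance
    isolated = config.isolated_lung

    p0, v0, n0, c_wall, p_atm = _pleural_coeffs(config)
    v_gas0 = config.chest_wall.pleural_gas_volume
    g_base = v_gas0 + v0 - c_wall * p0  # g = g_base - V + w
    if not isolated:
        inv_rv = 1.0 / config.abdomen.valve_resistance
        k_w = config.abdomen.static_elastance / 1000.0
        neg_p0 = -p0

    state = initial or initial_state_at_frc(config)
    v = state.lung_volume
    w = state.displaced_water

    n_breaths_total = sum(n for _, n in peep_schedule)
    n_samples = n_breaths_total * spb
    paw = np.empty(n_samples)
    ppl = np.empty(n_samples)
    vtrace = np.empty(n_samples + 1)
    phase = np.tile(phase_rec, n_breaths_total)

    transitions: list[PeepTransition] = []
    current_peep = peep_schedule[0][0]
    breath_idx = 0
    sample_idx = 0
    half = dt * 0.5
    sixth = dt / 6.0

    for level_peep, n_breaths in peep_schedule:
        if breath_idx > 0 and level_peep != current_peep:
            transitions.append(
                PeepTransition(
                    sample=breath_idx * spb,
                    breath=breath_idx,
                    old_peep=current_peep,
                    new_peep=level_peep,
                )
            )
        current_peep = level_peep
        peep = level_peep

        for _ in range(n_breaths):
            sub = 0
            for s in range(spb):
                ph = phase_sub_l[sub]
                # --- record channels at the sample instant -------------
                if isolated:
                    p_pl = 0.0
                else:
                    g = g_base - v + w
                    if c_wall == 0.0:
                        p_pl = n0 / g - p_atm
                    else:
                        b = g + c_wall * p_atm
                        p_pl = 2.0 * (p_atm * g - n0) / (-b - math.sqrt(b * b - 4.0 * c_wall * (p_atm * g - n0)))
                p_alv = v * inv_cl + p_pl
                if ph == 0:
                    rec_paw = p_alv + q_insp * r_aw
                elif ph == 1:
                    rec_paw = p_alv
                else:
                    rec_paw = peep + (p_alv - peep) * r_exp_frac if p_alv > peep else p_alv
                paw[sample_idx] = rec_paw
                ppl[sample_idx] = p_pl
                vtrace[sample_idx] = v
                sample_idx += 1
                # --- integrate n_sub substeps --------------------------
                for _j in range(n_sub):
                    ph = phase_sub_l[sub]
                    if isolated:
                        if ph == 0:
                            v += q_insp * dt
                        elif ph == 2:
                            # exact scalar RK4 on v alone
                            def dv_iso(vv: float) -> float:
                                pa = vv * inv_cl
                                return -(pa - peep) * inv_rt if pa > peep else 0.0
                            k1 = dv_iso(v)
                            k2 = dv_iso(v + half * k1)
                            k3 = dv_iso(v + half * k2)
                            k4 = dv_iso(v + dt * k3)
                            v += sixth * (k1 + 2 * k2 + 2 * k3 + k4)
                        sub += 1
                        continue
                    # coupled RK4 on (v, w)
                    vv, ww = v, w
                    for stage in range(4):
                        g = g_base - vv + ww
                        if c_wall == 0.0:
                            p_pl = n0 / g - p_atm
                        else:
                            b = g + c_wall * p_atm
                            cq = p_atm * g - n0
                            p_pl = 2.0 * cq / (-b - math.sqrt(b * b - 4.0 * c_wall * cq))
                        if ph == 0:
                            dv = q_insp
                        elif ph == 1:
                            dv = 0.0
                        else:
                            p_alv = vv * inv_cl + p_pl
                            dv = -(p_alv - peep) * inv_rt if p_alv > peep else 0.0
                        dw = (p_pl + neg_p0 - k_w * ww) * inv_rv
                        if stage == 0:
                            k1v, k1w = dv, dw
                            vv, ww = v + half * dv, w + half * dw
                        elif stage == 1:
                            k2v, k2w = dv, dw
                            vv, ww = v + half * dv, w + half * dw
                        elif stage == 2:
                            k3v, k3w = dv, dw
                            vv, ww = v + dt * dv, w + dt * dw
                        else:
                            v += sixth * (k1v + 2 * k2v + 2 * k3v + dv)
                            w += sixth * (k1w + 2 * k2w + 2 * k3w + dw)
                    sub += 1
                if v > capacity:
                    raise CapacityError(
                        f"lung volume {v:.1f} ml exceeds capacity {capacity:.0f} ml "
                        f"at PEEP {peep:g} cmH2O"
                    )
            breath_idx += 1
    vtrace[n_samples] = v

    flow = (vtrace[1:] - vtrace[:-1]) * config.record_rate
    wf = Waveforms(
        sample_rate=config.record_rate,
        paw=paw,
        ppl=ppl,
        flow=flow,
        vlung=vtrace[:n_samples].copy(),
        phase=phase,
        transitions=transitions,
        samples_per_breath=spb,
        meta={
            "n_lungs": lung.n_units,
            "strapped": config.chest_wall.strapped,
            "isolated": isolated,
            "schedule": list(peep_schedule),
            "final_state": (v, w),
        },
    )
    return wf


def simulate_cpap(config: ModelConfig, peep: float, duration: float) -> ModelState:
    """Hold the airway at a constant pressure (no tidal cycling).

    Long runs converge to :func:`equilibrium_solver` — the absolute
    oracle-equivalence check, free of the ventilated-cycle DC offset.
    """
    cfg = config.replace(
        ventilator=config.ventilator.__class__(
            tidal_volume=0.0,
            respiratory_rate=config.ventilator.respiratory_rate,
            ie_ratio=config.ventilator.ie_ratio,
            pause_fraction=config.ventilator.pause_fraction,
            peep=peep,
            expiratory_resistance=config.ventilator.expiratory_resistance,
        )
    )
    # with VT = 0 every phase is passive; expiration logic vents only above
    # PEEP, so inflate through a symmetric passive path instead: treat the
    # airway as clamped at `peep` behind the airway resistance.
    dt = cfg.integrator_dt
    n = round(duration / dt)
    lung = cfg.lung
    inv_cl = 1.0 / lung.total_compliance
    r = lung.airway_resistance + cfg.ventilator.expiratory_resistance
    inv_r = 1.0 / r
    isolated = cfg.isolated_lung
    p0, v0, n0, c_wall, p_atm = _pleural_coeffs(cfg)
    g_base = cfg.chest_wall.pleural_gas_volume + v0 - c_wall * p0
    if not isolated:
        inv_rv = 1.0 / cfg.abdomen.valve_resistance
        k_w = cfg.abdomen.static_elastance / 1000.0
    state = initial_state_at_frc(cfg)
    v, w = state.lung_volume, state.displaced_water
    half, sixth = dt * 0.5, dt / 6.0

    def deriv(vv: float, ww: float) -> tuple[float, float]:
        if isolated:
            p_pl = 0.0
        else:
            g = g_base - vv + ww
            if c_wall == 0.0:
                p_pl = n0 / g - p_atm
            else:
                b = g + c_wall * p_atm
                cq = p_atm * g - n0
                p_pl = 2.0 * cq / (-b - math.sqrt(b * b - 4.0 * c_wall * cq))
        dv = (peep - (vv * inv_cl + p_pl)) * inv_r
        dw = 0.0 if isolated else (p_pl - p0 - k_w * ww) * inv_rv
        return dv, dw

    for _ in range(n):
        k1v, k1w = deriv(v, w)
        k2v, k2w = deriv(v + half * k1v, w + half * k1w)
        k3v, k3w = deriv(v + half * k2v, w + half * k2w)
        k4v, k4w = deriv(v + dt * k3v, w + dt * k3w)
        v += sixth * (k1v + 2 * k2v + 2 * k3v + k4v)
        w += sixth * (k1w + 2 * k2w + 2 * k3w + k4w)
        if v > lung.total_capacity:
            raise CapacityError("lung volume exceeds capacity during CPAP run")
    p_pl = pleural_pressure_of(cfg, v, w)
    return ModelState(
        time=duration,
        lung_volume=v,
        displaced_water=w,
        pleural_pressure=p_pl,
        airway_pressure=peep,
        ventilator_phase="pause",
    )


# ---------------------------------------------------------------------------
# Chest-wall calibration
# ---------------------------------------------------------------------------

def measure_tidal_ecw(config: ModelConfig, peep: float = 0.0, n_breaths: int = 12) -> float:
    """Simulated tidal chest-wall elastance ΔPPL/VT (cmH2O/L) at a PEEP.

    Ventilates the model to a periodic steady state and reads the plateau
    (last 100 ms of the pause) minus end-expiratory (last 100 ms of
    expiration) pleural pressures of the final breath.
    """
    schedule = [(0.0, n_breaths), (peep, 25)] if peep > 0 else [(0.0, n_breaths)]
    wf = simulate(config, schedule)
    spb = wf.samples_per_breath
    timing = cycle_timing(config.ventilator)
    n_win = round(0.1 * wf.sample_rate)
    i_pause_end = round((timing.flow_time + timing.pause_time) * wf.sample_rate)
    last = len(wf) - spb  # start of final breath
    ppl_ei = float(np.mean(wf.ppl[last + i_pause_end - n_win : last + i_pause_end]))
    ppl_ee = float(np.mean(wf.ppl[last + spb - n_win : last + spb]))
    return (ppl_ei - ppl_ee) / config.ventilator.tidal_volume * 1000.0


def calibrate_chest_wall(
    config: ModelConfig,
    target_tidal_ecw: float,
    tol: float = 0.2,
    bracket: tuple[float, float] = (2.0, 300.0),
) -> ModelConfig:
    """Adjust wall compliance until tidal ΔPPL/VT at ZEEP matches the target.

    Deterministic bisection with a fixed bracket; valve resistance is held
    fixed.  Tidal chest-wall elastance decreases monotonically with wall
    compliance.  Raises :class:`CalibrationError` if the target lies outside
    the bracket.
    """
    if target_tidal_ecw <= config.abdomen.static_elastance:
        raise CalibrationError(
            "target tidal elastance must exceed the static chest-wall elastance"
        )

    def measured(c_wall: float) -> float:
        cfg = config.replace(
            chest_wall=config.chest_wall.__class__(
                pleural_gas_volume=config.chest_wall.pleural_gas_volume,
                wall_compliance=c_wall,
                strapped=config.chest_wall.strapped,
                atmospheric_pressure=config.chest_wall.atmospheric_pressure,
                evacuation_pressure=config.chest_wall.evacuation_pressure,
            )
        )
        return measure_tidal_ecw(cfg)

    current = measure_tidal_ecw(config)
    if abs(current - target_tidal_ecw) <= tol:
        return config

    lo, hi = bracket
    f_lo = measured(lo) - target_tidal_ecw  # stiff wall -> high elastance
    f_hi = measured(hi) - target_tidal_ecw
    if f_lo < 0 or f_hi > 0:
        raise CalibrationError(
            f"target {target_tidal_ecw} cmH2O/L unattainable within wall-compliance "
            f"bracket {bracket}"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        f_mid = measured(mid) - target_tidal_ecw
        if abs(f_mid) <= 0.25 * tol or (hi - lo) < 1e-3:
            lo = hi = mid
            break
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    c_wall = 0.5 * (lo + hi)
    out = config.replace(
        chest_wall=config.chest_wall.__class__(
            pleural_gas_volume=config.chest_wall.pleural_gas_volume,
            wall_compliance=c_wall,
            strapped=config.chest_wall.strapped,
            atmospheric_pressure=config.chest_wall.atmospheric_pressure,
            evacuation_pressure=config.chest_wall.evacuation_pressure,
        )
    )
    if abs(measure_tidal_ecw(out) - target_tidal_ecw) > tol:
        raise CalibrationError("bisection did not reach the requested tolerance")
    return out
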