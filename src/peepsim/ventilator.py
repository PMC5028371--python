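"""Volume-controlled ventilation source and PEEP-regulated expiratory valve.

The ventilator delivers a square (constant-flow) inspiration, holds an
end-inspiratory pause, and opens a one-way expiratory valve that never lets
airway pressure fall below the set PEEP.  Phase boundaries are quantised to
the waveform record grid so that the delivered tidal volume and the 100-Hz
rectangle-summed spirometric volumes are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import VentilatorSettings

INSPIRATION, PAUSE, EXPIRATION = 0, 1, 2
PHASE_NAMES = {INSPIRATION: "inspiration", PAUSE: "pause", EXPIRATION: "expiration"}


@dataclass(frozen=True)
class CycleTiming:
    """Phase schedule of one breath, quantised to the record grid."""

    cycle_time: float
    flow_time: float  # constant-flow portion of inspiration
    pause_time: float
    expiratory_time: float
    inspiratory_flow: float  # ml/s during the flow portion

    def phase_at(self, t_in_cycle: float) -> int:
        if t_in_cycle < self.flow_time:
            return INSPIRATION
        if t_in_cycle < self.flow_time + self.pause_time:
            return PAUSE
        return EXPIRATION


def cycle_timing(settings: VentilatorSettings, grid: float = 0.01) -> CycleTiming:
    """Derive the breath schedule from the ventilator settings.

    The end-inspiratory pause is the terminal part of the inspiratory
    portion of the cycle, so the flow time is T_insp - T_pause.  Durations
    are rounded to ``grid`` (the 100-Hz record interval) and the inspiratory
    flow is set so that the delivered volume is exactly the set VT.
    """
    cycle = settings.cycle_time
    flow_time = settings.inspiratory_time - settings.pause_time
    q = round(flow_time / grid) * grid
    pause = round(settings.pause_time / grid) * grid
    total = round(cycle / grid) * grid
    if settings.tidal_volume == 0:  # constant-pressure (CPAP) degenerate mode
        q = 0.0
    if q <= 0 and settings.tidal_volume > 0:
        raise ValueError("inspiratory flow time must be positive")
    flow = settings.tidal_volume / q if q > 0 else 0.0
    return CycleTiming(
        cycle_time=total,
        flow_time=q,
        pause_time=pause,
        expiratory_time=total - q - pause,
        inspiratory_flow=flow,
    )


def breath_phase(settings: VentilatorSettings, t_in_cycle: float) -> tuple[str, float]:
    """Phase name and prescribed inspiratory flow at a time within the cycle.

    Returns ``(phase, flow)`` with flow in ml/s; flow is nonzero only during
    the constant-flow portion of inspiration.  Expiration is passive through
    the PEEP valve, so its prescribed flow is 0.
    """
    timing = cycle_timing(settings)
    if not 0 <= t_in_cycle < timing.cycle_time:
        raise ValueError("t_in_cycle must lie within one breathing cycle")
    code = timing.phase_at(t_in_cycle)
    flow = timing.inspiratory_flow if code == INSPIRATION else 0.0
    return PHASE_NAMES[code], flow


def expiratory_valve_flow(airway_pressure: float, settings: VentilatorSettings) -> float:
    """Expired flow (ml/s) through the one-way PEEP valve.

    The valve vents only pressure above the set PEEP; it never lets airway
    pressure fall below PEEP, so flow is clipped at zero.
    """
    return max(0.0, airway_pressure - settings.peep) / settings.expiratory_resistance
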