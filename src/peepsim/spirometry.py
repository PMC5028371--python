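"""Measurement layer: breath segmentation, tidal volumes, PEEP-change
detection and the cumulative ΔEELV estimator.

The change in end-expiratory lung volume after a PEEP change is estimated
purely from the flow signal, exactly as the bench software does: the
cumulative inspiratory-expiratory tidal-volume difference over the first 15
breaths at the new level, compensated for any constant flow-sensor offset
decided during the five breaths that follow the 15 included in the
summation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import NoiseSettings
from .ventilator import EXPIRATION, INSPIRATION, PAUSE
from .waveforms import Waveforms

#: Flow threshold (ml/s) and hold time (s) of the threshold-based
#: inspiration-onset detector used when no phase annotation is trusted.
FLOW_THRESHOLD = 25.0
HOLD_TIME = 0.1
#: Read-out window for end-expiratory / plateau pressures (s).
PRESSURE_WINDOW = 0.1
#: Measured PEEP difference (cmH2O) that flags a PEEP change.
PEEP_CHANGE_THRESHOLD = 1.0


class EstimationError(RuntimeError):
    """Not enough data to evaluate the estimator."""


@dataclass
class BreathRecord:
    """One detected breath and its measured pressure-volume landmarks."""

    index: int
    start: int  # sample index of inspiration onset
    end: int  # first sample of the next breath
    vti: float  # inspired volume, ml
    vte: float  # expired volume, ml
    paw_ee: float  # end-expiratory airway pressure (measured PEEP), cmH2O
    ppl_ee: float  # end-expiratory pleural pressure, cmH2O
    paw_ei: float  # end-inspiratory (pause plateau) airway pressure, cmH2O
    ppl_ei: float  # end-inspiratory pleural pressure, cmH2O

    @property
    def peep_measured(self) -> float:
        return self.paw_ee


def _onsets_from_phase(wf: Waveforms) -> np.ndarray:
    ph = wf.phase
    starts = np.flatnonzero((ph[1:] == INSPIRATION) & (ph[:-1] == EXPIRATION)) + 1
    if len(ph) and ph[0] == INSPIRATION:
        starts = np.concatenate([[0], starts])
    return starts


def _onsets_from_flow(wf: Waveforms) -> np.ndarray:
    hold = round(HOLD_TIME * wf.sample_rate)
    above = wf.flow >= FLOW_THRESHOLD
    # sustained crossing: below -> above, staying above for `hold` samples
    onsets = []
    i = 1
    n = len(above)
    while i < n - hold:
        if above[i] and not above[i - 1] and above[i : i + hold].all():
            onsets.append(i)
            i += hold
        else:
            i += 1
    if above[:hold].all():
        onsets.insert(0, 0)
    return np.asarray(onsets, dtype=int)


def segment_breaths(wf: Waveforms, method: str = "auto") -> list[BreathRecord]:
    """Delimit breaths at inspiration onsets and measure each one.

    ``method`` is ``"phase"`` (use the simulator's phase annotation),
    ``"threshold"`` (flow crossing +25 ml/s held for 100 ms, the noise-robust
    route) or ``"auto"`` (phase if present).  Tidal volumes are rectangle
    sums of the 100-Hz flow samples; pressures are means over the final
    100 ms of expiration (end-expiratory) and of the pause (plateau).
    Returns an empty list when no complete breath is present.
    """
    if method not in ("auto", "phase", "threshold"):
        raise ValueError(f"unknown segmentation method {method!r}")
    use_phase = method == "phase" or (method == "auto" and wf.phase is not None)
    onsets = _onsets_from_phase(wf) if use_phase else _onsets_from_flow(wf)
    if len(onsets) == 0:
        return []
    # close the final breath at the end of record if it is a full cycle
    spacing = wf.samples_per_breath or (
        int(np.median(np.diff(onsets))) if len(onsets) > 1 else None
    )
    bounds = list(onsets)
    if spacing is not None and len(wf) - onsets[-1] >= spacing:
        bounds.append(onsets[-1] + spacing)
    if len(bounds) < 2:
        return []

    n_win = round(PRESSURE_WINDOW * wf.sample_rate)
    dt = 1.0 / wf.sample_rate
    breaths = []
    for b, (i0, i1) in enumerate(zip(bounds[:-1], bounds[1:])):
        flow = wf.flow[i0:i1]
        vti = float(flow[flow > 0].sum() * dt)
        vte = float(-flow[flow < 0].sum() * dt)
        if use_phase:
            ph = wf.phase[i0:i1]
            pause_idx = np.flatnonzero(ph == PAUSE)
            i_plateau = i0 + (pause_idx[-1] + 1 if len(pause_idx) else int(np.argmax(ph == EXPIRATION)))
        else:
            exp_idx = np.flatnonzero(flow <= -FLOW_THRESHOLD)
            i_plateau = i0 + (exp_idx[0] if len(exp_idx) else len(flow))
        ee = slice(i1 - n_win, i1)
        ei = slice(max(i0, i_plateau - n_win), i_plateau)
        breaths.append(
            BreathRecord(
                index=b,
                start=int(i0),
                end=int(i1),
                vti=vti,
                vte=vte,
                paw_ee=float(wf.paw[ee].mean()),
                ppl_ee=float(wf.ppl[ee].mean()),
                paw_ei=float(wf.paw[ei].mean()),
                ppl_ei=float(wf.ppl[ei].mean()),
            )
        )
    return breaths


def breath_table(breaths: list[BreathRecord]) -> pd.DataFrame:
    """One row per breath, for CSV export."""
    return pd.DataFrame([vars(b) for b in breaths])


def detect_peep_changes(
    wf: Waveforms, breaths: list[BreathRecord] | None = None
) -> list[tuple[int, float, float]]:
    """Flag breaths whose measured PEEP differs from the previous breath's.

    Measured PEEP is the mean airway pressure over the final 100 ms of
    expiration.  Returns ``(breath_index, old_peep, new_peep)`` for each
    change larger than 1 cmH2O; an empty list for a constant-PEEP run.
    """
    breaths = breaths if breaths is not None else segment_breaths(wf)
    changes = []
    for prev, cur in zip(breaths[:-1], breaths[1:]):
        if abs(cur.paw_ee - prev.paw_ee) > PEEP_CHANGE_THRESHOLD:
            changes.append((cur.index, prev.paw_ee, cur.paw_ee))
    return changes


def delta_eelv(
    wf: Waveforms,
    change_breath: int,
    breaths: list[BreathRecord] | None = None,
    n_sum: int = 15,
    n_offset: int = 5,
) -> float:
    """Cumulative ΔEELV (ml) following the PEEP change at ``change_breath``.

    Sums ``VTi - VTe`` over the first ``n_sum`` breaths at the new level and
    subtracts ``n_sum`` times the per-breath offset, where the offset is the
    mean ``VTi - VTe`` over the ``n_offset`` breaths that follow the
    summation window.  Positive for PEEP increases.  Raises
    :class:`EstimationError` when fewer than ``n_sum + n_offset`` breaths
    follow the change.
    """
    breaths = breaths if breaths is not None else segment_breaths(wf)
    need = n_sum + n_offset
    window = [b for b in breaths if change_breath <= b.index < change_breath + need]
    if len(window) < need:
        raise EstimationError(
            f"need {need} breaths after the PEEP change, found {len(window)}"
        )
    diffs = [b.vti - b.vte for b in window]
    offset = float(np.mean(diffs[n_sum:]))
    return float(sum(diffs[:n_sum]) - n_sum * offset)


def add_noise(wf: Waveforms, noise: NoiseSettings) -> Waveforms:
    """Inject sensor noise: Gaussian per sample on flow and pressures plus a
    constant flow offset.  Deterministic under a fixed seed; the ground-truth
    lung-volume channel is never touched."""
    out = wf.copy()
    if noise.silent:
        return out
    rng = np.random.default_rng(noise.seed)
    n = len(wf)
    if noise.pressure_noise_sd > 0:
        out.paw = out.paw + rng.normal(0.0, noise.pressure_noise_sd, n)
        out.ppl = out.ppl + rng.normal(0.0, noise.pressure_noise_sd, n)
    if noise.flow_noise_sd > 0:
        out.flow = out.flow + rng.normal(0.0, noise.flow_noise_sd, n)
    if noise.flow_offset != 0.0:
        out.flow = out.flow + noise.flow_offset
    out.meta["noise"] = vars(noise).copy()
    return out
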