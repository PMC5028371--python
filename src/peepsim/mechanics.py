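"""Elastances, transpulmonary pressures and the measured-vs-predicted
ΔEELV regression.

Two routes to the lung's distending pressure are implemented side by side:

* conventional: tidal transpulmonary driving pressure ΔPAW - ΔPPL, which
  needs a pleural (esophageal) pressure signal;
* PEEP-step: lung elastance as ΔPEEP/ΔEELV from a simple PEEP change and
  spirometry alone, so the transpulmonary driving pressure of a tidal
  volume is (ΔPEEP/ΔEELV) x VT — no pleural pressure required.

The central quantitative claim is that the two agree because the
end-expiratory pleural pressure barely rises with PEEP (the chest-wall
analogue's spring-out behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .spirometry import BreathRecord, delta_eelv, detect_peep_changes, segment_breaths
from .waveforms import Waveforms


class MechanicsError(ValueError):
    pass


@dataclass(frozen=True)
class TidalElastances:
    """Tidal elastances of one breath, cmH2O/L.

    ``etot = dpaw/vt``, ``ecw = dppl/vt``, ``el = (dpaw - dppl)/vt``; the
    identity ``etot = ecw + el`` holds exactly.  Pressure deltas are
    end-inspiratory pause plateau minus end-expiratory values; the volume is
    the inspired tidal volume.
    """

    dpaw: float
    dppl: float
    vt: float
    etot: float
    ecw: float
    el: float

    @property
    def dptp(self) -> float:
        """Tidal transpulmonary driving pressure ΔPAW - ΔPPL, cmH2O."""
        return self.dpaw - self.dppl


def tidal_elastances_from(dpaw: float, dppl: float, vt: float) -> TidalElastances:
    if vt <= 0:
        raise MechanicsError("tidal volume must be positive to define elastances")
    vt_l = vt / 1000.0
    return TidalElastances(
        dpaw=dpaw,
        dppl=dppl,
        vt=vt,
        etot=dpaw / vt_l,
        ecw=dppl / vt_l,
        el=(dpaw - dppl) / vt_l,
    )


def tidal_elastances(breath: BreathRecord) -> TidalElastances:
    """Tidal total, chest-wall and lung elastances of one breath."""
    return tidal_elastances_from(
        dpaw=breath.paw_ei - breath.paw_ee,
        dppl=breath.ppl_ei - breath.ppl_ee,
        vt=breath.vti,
    )


@dataclass(frozen=True)
class PeepStepResult:
    """One PEEP step: ΔPEEP, ΔEELV and the derived quantities."""

    arm: str
    dpeep: float  # measured, cmH2O
    deelv: float  # ml
    el_peepstep: float  # ΔPEEP/ΔEELV, cmH2O/L
    dppl_ee: float  # cmH2O
    dptp_ee: float  # = dpeep - dppl_ee, cmH2O
    ecw_ee: float  # ΔPPL_EE/ΔEELV, cmH2O/L


def peepstep_result(
    dpeep: float, deelv: float, dppl_ee: float, arm: str = ""
) -> PeepStepResult:
    """Assemble a PEEP-step result from its three measured inputs."""
    if deelv == 0:
        raise MechanicsError("ΔEELV must be nonzero to form elastances")
    return PeepStepResult(
        arm=arm,
        dpeep=dpeep,
        deelv=deelv,
        el_peepstep=dpeep / deelv * 1000.0,
        dppl_ee=dppl_ee,
        dptp_ee=dpeep - dppl_ee,
        ecw_ee=dppl_ee / deelv * 1000.0,
    )


def driving_ptp_via_peepstep(dpaw: float, ecw: float, vt: float) -> float:
    """Transpulmonary driving pressure as ΔPAW - ECW x VT (cmH2O).

    ``ecw`` in cmH2O/L, ``vt`` in ml.  With the chest-wall elastance taken
    from a PEEP step (ETOT - ΔPEEP/ΔEELV) this needs no pleural pressure.
    """
    return dpaw - ecw * vt / 1000.0


def ptp_from_peepstep(dpeep: float, deelv: float, vt: float) -> float:
    """End-inspiratory transpulmonary pressure as (ΔPEEP/ΔEELV) x VT."""
    if deelv == 0:
        raise MechanicsError("ΔEELV must be nonzero")
    return dpeep / deelv * vt


# ---------------------------------------------------------------------------
# P/V points
# ---------------------------------------------------------------------------

@dataclass
class PVPoints:
    """Per-breath end-expiratory and end-inspiratory P/V pairs plus the
    best-fit lung line through the end-expiratory airway points."""

    eelv: np.ndarray  # ml, end-expiratory lung volume per breath
    paw_ee: np.ndarray
    ptp_ee: np.ndarray
    eilv: np.ndarray  # ml, end-inspiratory lung volume
    paw_ei: np.ndarray
    ptp_ei: np.ndarray
    slope: float  # cmH2O/L, fitted on end-expiratory airway points
    intercept: float  # cmH2O
    max_residual: float  # cmH2O


def pv_points(wf: Waveforms, breaths: list[BreathRecord] | None = None) -> PVPoints:
    """Extract P/V landmark points and fit the lung line.

    The line is the least-squares fit of end-expiratory airway pressure
    against end-expiratory lung volume; its slope estimates the elastance
    governing PEEP inflation.  Requires at least two distinct PEEP levels.
    """
    breaths = breaths if breaths is not None else segment_breaths(wf)
    if not breaths:
        raise MechanicsError("no breaths to extract P/V points from")
    n_win = round(0.1 * wf.sample_rate)
    eelv, eilv, paw_ee, paw_ei, ptp_ee, ptp_ei = [], [], [], [], [], []
    for b in breaths:
        ee = slice(b.end - n_win, b.end)
        eelv.append(float(wf.vlung[ee].mean()))
        paw_ee.append(b.paw_ee)
        ptp_ee.append(b.paw_ee - b.ppl_ee)
        i_pk = b.start + int(np.argmax(wf.vlung[b.start : b.end]))
        eilv.append(float(wf.vlung[i_pk]))
        paw_ei.append(b.paw_ei)
        ptp_ei.append(b.paw_ei - b.ppl_ei)
    paw_ee_a = np.asarray(paw_ee)
    eelv_a = np.asarray(eelv)
    if np.ptp(paw_ee_a) < 1.0:
        raise MechanicsError("P/V line fit needs at least two distinct PEEP levels")
    slope_ml, intercept = np.polyfit(eelv_a, paw_ee_a, 1)
    resid = paw_ee_a - (slope_ml * eelv_a + intercept)
    return PVPoints(
        eelv=eelv_a,
        paw_ee=paw_ee_a,
        ptp_ee=np.asarray(ptp_ee),
        eilv=np.asarray(eilv),
        paw_ei=np.asarray(paw_ei),
        ptp_ei=np.asarray(ptp_ei),
        slope=float(slope_ml * 1000.0),
        intercept=float(intercept),
        max_residual=float(np.max(np.abs(resid))),
    )


# ---------------------------------------------------------------------------
# Measured-vs-predicted ΔEELV regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    """Zero-intercept fit Y = bX of measured on predicted ΔEELV, with the
    free-intercept fit reported alongside for transparency."""

    slope: float
    r2: float
    n: int
    slope_free: float
    intercept_free: float
    r2_free: float


def eelv_regression(measured: np.ndarray, predicted: np.ndarray) -> RegressionResult:
    """Regress spirometric ΔEELV on ΔPEEP/EL (both ml), intercept fixed at 0.

    Requires at least 3 steps and a non-degenerate predictor.
    """
    y = np.asarray(measured, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if len(x) < 3:
        raise MechanicsError("regression needs at least 3 PEEP steps")
    if np.all(x == 0):
        raise MechanicsError("degenerate predictor")
    through_origin = sm.OLS(y, x[:, None]).fit()
    free = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(through_origin.params[0]),
        r2=float(through_origin.rsquared),
        n=len(x),
        slope_free=float(free.params[1]),
        intercept_free=float(free.params[0]),
        r2_free=float(free.rsquared),
    )


def brute_force_origin_slope(
    measured: np.ndarray, predicted: np.ndarray, grid: int = 2_000_001, span: float = 2.0
) -> float:
    """Slope by grid minimisation of the squared error (oracle for tests)."""
    x = np.asarray(predicted, float)
    y = np.asarray(measured, float)
    bs = np.linspace(0.0, span, grid)
    sse = (y * y).sum() - 2 * bs * (x * y).sum() + bs * bs * (x * x).sum()
    return float(bs[np.argmin(sse)])


# ---------------------------------------------------------------------------
# statsmodels-flavoured analysis front end
# ---------------------------------------------------------------------------

@dataclass
class StepMeasurement:
    """Everything measured around one detected PEEP change."""

    arm: str
    breath: int
    dpeep: float
    deelv: float
    dppl_ee: float
    dptp_ee: float
    el_peepstep: float
    ecw_ee: float
    el_tidal: float  # from tidal ΔPAW-ΔPPL at the pre-change level
    ecw_tidal: float
    etot_tidal: float
    vt: float
    deelv_predicted: float  # ΔPEEP / EL_tidal, ml
    deelv_truth: float  # from the ground-truth lung-volume channel, ml


class PeepStepModel:
    """Lung-mechanics estimation from a ventilator waveform record.

    Parameters
    ----------
    waveforms : Waveforms
        A record containing at least one PEEP change with >= 20 breaths at
        each level.
    arm : str
        Label carried into the results (e.g. ``"2L/normal"``).

    ``fit()`` segments breaths, detects PEEP changes, runs the 15-breath
    cumulative ΔEELV estimator for each change and derives tidal and
    end-expiratory elastances and transpulmonary pressures.
    """

    def __init__(self, waveforms: Waveforms, arm: str = "") -> None:
        self.waveforms = waveforms
        self.arm = arm

    @classmethod
    def from_waveforms(cls, waveforms: Waveforms, arm: str = "") -> "PeepStepModel":
        return cls(waveforms, arm=arm)

    def fit(self, settle_breaths: int = 3) -> "PeepStepResults":
        wf = self.waveforms
        breaths = segment_breaths(wf)
        raw = detect_peep_changes(wf, breaths)
        # A large step onto a low-elastance lung can exceed the previous
        # plateau pressure: the first expiration never opens the valve, the
        # measured PEEP settles over two breaths and the detector flags the
        # same transition twice.  Merge flags closer than 4 breaths into one
        # event anchored at its first breath.
        changes: list[tuple[int, float, float]] = []
        for c in raw:
            if changes and c[0] - changes[-1][0] <= 3:
                continue
            changes.append(c)
        level_bounds = [0] + [b for b, _, _ in changes] + [len(breaths)]
        steps: list[StepMeasurement] = []
        for i, (b, _old, _new) in enumerate(changes):
            lo_prev = level_bounds[i]
            hi_next = level_bounds[i + 2]
            pre = breaths[max(lo_prev, b - settle_breaths) : b]
            post = breaths[max(b, hi_next - settle_breaths) : hi_next]
            dpeep = float(np.mean([x.paw_ee for x in post]) - np.mean([x.paw_ee for x in pre]))
            dppl = float(np.mean([x.ppl_ee for x in post]) - np.mean([x.ppl_ee for x in pre]))
            deelv = delta_eelv(wf, b, breaths)
            tidal = [tidal_elastances(x) for x in pre]
            el_tidal = float(np.mean([t.el for t in tidal]))
            ecw_tidal = float(np.mean([t.ecw for t in tidal]))
            etot_tidal = float(np.mean([t.etot for t in tidal]))
            vt = float(np.mean([x.vti for x in pre]))
            n_win = round(0.1 * wf.sample_rate)
            v_pre = float(np.mean([wf.vlung[x.end - n_win : x.end].mean() for x in pre]))
            v_post = float(np.mean([wf.vlung[x.end - n_win : x.end].mean() for x in post]))
            res = peepstep_result(dpeep, deelv, dppl, arm=self.arm)
            steps.append(
                StepMeasurement(
                    arm=self.arm,
                    breath=b,
                    dpeep=dpeep,
                    deelv=deelv,
                    dppl_ee=dppl,
                    dptp_ee=res.dptp_ee,
                    el_peepstep=res.el_peepstep,
                    ecw_ee=res.ecw_ee,
                    el_tidal=el_tidal,
                    ecw_tidal=ecw_tidal,
                    etot_tidal=etot_tidal,
                    vt=vt,
                    deelv_predicted=dpeep / el_tidal * 1000.0,
                    deelv_truth=v_post - v_pre,
                )
            )
        return PeepStepResults(self, steps)


@dataclass
class PeepStepResults:
    """Per-step estimates with uncertainties deferred to pooling."""

    model: PeepStepModel
    steps: list[StepMeasurement] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def regression(self) -> RegressionResult:
        frame = self.to_frame()
        return eelv_regression(
            frame["deelv"].to_numpy(), frame["deelv_predicted"].to_numpy()
        )

    def summary(self) -> str:
        lines = [
            "PEEP-step mechanics" + (f" — arm {self.model.arm}" if self.model.arm else ""),
            f"{'breath':>6} {'dPEEP':>7} {'dEELV':>8} {'EL(step)':>9} "
            f"{'EL(tidal)':>9} {'dPPL_EE':>8} {'dPTP_EE':>8} {'ECW_EE':>7}",
        ]
        for s in self.steps:
            lines.append(
                f"{s.breath:>6d} {s.dpeep:>7.2f} {s.deelv:>8.1f} {s.el_peepstep:>9.2f} "
                f"{s.el_tidal:>9.2f} {s.dppl_ee:>8.2f} {s.dptp_ee:>8.2f} {s.ecw_ee:>7.2f}"
            )
        if len(self.steps) >= 3:
            reg = self.regression()
            lines.append(
                f"zero-intercept regression: Y = {reg.slope:.3f} X, r2 = {reg.r2:.4f} "
                f"(n = {reg.n})"
            )
        return "\n".join(lines)


def pooled_summary(frames: list[pd.DataFrame], by: str = "nominal_step") -> pd.DataFrame:
    """Mean +/- SD across arms, triplicate-averaged per arm first.

    Each input frame is one arm's step table (with a ``nominal_step``
    column); repetitions within an arm are averaged before pooling, matching
    the bench statistics.
    """
    per_arm = []
    for frame in frames:
        grouped = frame.groupby(by, as_index=False).mean(numeric_only=True)
        per_arm.append(grouped)
    allarms = pd.concat(per_arm, ignore_index=True)
    agg = allarms.groupby(by).agg(["mean", "std"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
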