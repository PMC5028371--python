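"""End-to-end study pipelines: run the standard experimental arms and pool
the results the way the bench analysis does.

The six arms are one, two or three parallel test lungs with a normal or
stiff (strapped) chest wall.  Paired PEEP steps go 0-X-0; the measured step
sizes of the bench were 4.4, 8.4 and 12.2 cmH2O and are used as the
commanded levels here (the simulator's expiratory valve regulates exactly,
so commanded and measured levels coincide to within hundredths).  The
incremental sequence steps 0-4.1-8.2-12.3 (each measured step 4.1 cmH2O).
Steps whose end-inspiratory volume would exceed the test-lung capacity are
omitted, as on the bench (single lung: highest step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mechanics import PeepStepModel, RegressionResult, StepMeasurement, eelv_regression
from .model import calibrate_chest_wall, measure_tidal_ecw
from .params import ModelConfig, NoiseSettings, make_default_config
from .protocols import ProtocolSpec, run_protocol

#: The six experimental arms: (n test lungs, chest-wall mode).
ARMS: list[tuple[int, str]] = [
    (n, mode) for n in (1, 2, 3) for mode in ("normal", "stiff")
]

#: Measured paired PEEP-step sizes (cmH2O) of the bench procedure.
PAIRED_STEPS: tuple[float, ...] = (4.4, 8.4, 12.2)

#: Incremental PEEP sequence (cmH2O); each measured step is 4.1 cmH2O.
INCREMENTAL_LEVELS: tuple[float, ...] = (0.0, 4.1, 8.2, 12.3)


def arm_label(n_lungs: int, mode: str) -> str:
    return f"{n_lungs}L/{mode}"


@dataclass
class StudyRun:
    """Pooled step measurements of a whole multi-arm procedure."""

    steps: pd.DataFrame  # one row per (arm, step, direction)
    omissions: list[tuple[str, float, str]] = field(default_factory=list)


def _steps_frame(measurements: list[dict]) -> pd.DataFrame:
    cols = [
        "arm", "n_lungs", "mode", "nominal_step", "direction", "breath",
        "dpeep", "deelv", "dppl_ee", "dptp_ee", "el_peepstep", "ecw_ee",
        "el_tidal", "ecw_tidal", "etot_tidal", "vt", "deelv_predicted",
        "deelv_truth",
    ]
    return pd.DataFrame(measurements, columns=cols)


def _collect(
    arm: tuple[int, str],
    nominal: float,
    fitted: list[StepMeasurement],
) -> list[dict]:
    n, mode = arm
    rows = []
    for s in fitted:
        rows.append(
            {
                "arm": arm_label(n, mode),
                "n_lungs": n,
                "mode": mode,
                "nominal_step": nominal,
                "direction": "up" if s.dpeep > 0 else "down",
                **{k: getattr(s, k) for k in (
                    "breath", "dpeep", "deelv", "dppl_ee", "dptp_ee",
                    "el_peepstep", "ecw_ee", "el_tidal", "ecw_tidal",
                    "etot_tidal", "vt", "deelv_predicted", "deelv_truth",
                )},
            }
        )
    return rows


def run_paired_step_suite(
    steps: tuple[float, ...] = PAIRED_STEPS,
    arms: list[tuple[int, str]] = ARMS,
    breaths_per_level: int = 25,
    noise: NoiseSettings | None = None,
    seed: int = 0,
    repetitions: int = 1,
) -> StudyRun:
    """Run 0-X-0 paired PEEP steps for every arm and step size.

    Returns one row per detected PEEP change (up and down separately).
    With noise enabled, repetitions are averaged per (arm, step, direction)
    before pooling, matching the bench's triplicate averaging.
    """
    rows: list[dict] = []
    omissions: list[tuple[str, float, str]] = []
    for arm in arms:
        n, mode = arm
        config = make_default_config(n, mode)
        for x in steps:
            spec = ProtocolSpec(
                peep_sequence=[0.0, x, 0.0],
                breaths_per_level=breaths_per_level,
                repetitions=repetitions,
                noise=noise,
                seed=seed,
                name=f"{arm_label(n, mode)} 0-{x:g}-0",
            )
            result = run_protocol(config, spec)
            for level, reason in result.omitted:
                omissions.append((arm_label(n, mode), level, reason))
            if result.omitted:
                continue
            rep_rows: list[pd.DataFrame] = []
            for wf in result.repetitions:
                fitted = PeepStepModel(wf, arm=arm_label(n, mode)).fit().steps
                rep_rows.append(_steps_frame(_collect(arm, x, fitted)))
            if repetitions > 1:
                merged = (
                    pd.concat(rep_rows)
                    .groupby(["arm", "nominal_step", "direction"], as_index=False)
                    .agg({c: "mean" for c in rep_rows[0].columns if rep_rows[0][c].dtype.kind == "f"}
                         | {"n_lungs": "first", "mode": "first", "breath": "first"})
                )
                rows.extend(merged.to_dict("records"))
            else:
                rows.extend(rep_rows[0].to_dict("records"))
    return StudyRun(steps=_steps_frame(rows), omissions=omissions)


def run_incremental_suite(
    levels: tuple[float, ...] = INCREMENTAL_LEVELS,
    arms: list[tuple[int, str]] = ARMS,
    breaths_per_level: int = 25,
    seed: int = 0,
) -> StudyRun:
    """Run the incremental PEEP staircase on every arm."""
    rows: list[dict] = []
    omissions: list[tuple[str, float, str]] = []
    for arm in ARMS if arms is None else arms:
        n, mode = arm
        config = make_default_config(n, mode)
        spec = ProtocolSpec(
            peep_sequence=list(levels),
            breaths_per_level=breaths_per_level,
            repetitions=1,
            seed=seed,
            name=f"{arm_label(n, mode)} incremental",
        )
        result = run_protocol(config, spec)
        for level, reason in result.omitted:
            omissions.append((arm_label(n, mode), level, reason))
        fitted = PeepStepModel(result.waveforms, arm=arm_label(n, mode)).fit().steps
        rows.extend(_collect(arm, float("nan"), fitted))
    return StudyRun(steps=_steps_frame(rows), omissions=omissions)


# ---------------------------------------------------------------------------
# Pooled quantities (the Results-paragraph numbers)
# ---------------------------------------------------------------------------

def transmission_by_step(suite: StudyRun) -> pd.DataFrame:
    """Mean (+/- SD across arms) end-expiratory ΔPTP and ΔPEEP per step size,
    up-steps only, pooled over the arms that ran the step."""
    up = suite.steps[suite.steps.direction == "up"]
    agg = up.groupby("nominal_step").agg(
        dpeep_mean=("dpeep", "mean"),
        dptp_ee_mean=("dptp_ee", "mean"),
        dptp_ee_sd=("dptp_ee", "std"),
        dppl_ee_mean=("dppl_ee", "mean"),
        deelv_mean=("deelv", "mean"),
        n_arms=("arm", "nunique"),
    )
    return agg.reset_index()


def incremental_means(suite: StudyRun) -> tuple[float, float, float]:
    """Mean per-step (ΔPEEP, ΔPTP_EE, ΔPPL_EE) over the incremental runs."""
    up = suite.steps[suite.steps.direction == "up"]
    return (
        float(up.dpeep.mean()),
        float(up.dptp_ee.mean()),
        float(up.dppl_ee.mean()),
    )


def regression_all_steps(suite: StudyRun) -> RegressionResult:
    """Measured vs ΔPEEP/EL_tidal ΔEELV over every arm and step (signed)."""
    frame = suite.steps
    return eelv_regression(
        frame["deelv"].to_numpy(), frame["deelv_predicted"].to_numpy()
    )


def ecw_ee_pooled(suite: StudyRun, nominal_step: float = 12.2) -> tuple[float, float]:
    """Pooled end-expiratory chest-wall elastance (cmH2O/L) and compliance
    (ml/cmH2O) over the 0-to-highest PEEP range, up-steps only."""
    up = suite.steps[
        (suite.steps.direction == "up") & (suite.steps.nominal_step == nominal_step)
    ]
    elastance = float(up.ecw_ee.mean())
    compliance = float((up.deelv / up.dppl_ee).mean())
    return elastance, compliance


def calibration_consistency(
    mode: str, target: float, eval_peep: float = 8.0
) -> tuple[float, float]:
    """Calibrate tidal chest-wall elastance at ZEEP, re-measure at a PEEP.

    Returns (elastance at ZEEP after calibration, elastance at eval_peep).
    Uses the two-lung configuration, where the bench numbers were reported.
    """
    config = make_default_config(2, mode)
    calibrated = calibrate_chest_wall(config, target, tol=0.2)
    at_zeep = measure_tidal_ecw(calibrated)
    at_peep = measure_tidal_ecw(calibrated, peep=eval_peep)
    return at_zeep, at_peep


def results_summary(
    paired: StudyRun | None = None, breaths_per_level: int = 25, seed: int = 0
) -> pd.DataFrame:
    """The pooled Results table: per step size, measured ΔPEEP, ΔEELV,
    ΔPPL_EE, ΔPTP_EE and the derived elastances, mean +/- SD across arms."""
    suite = paired or run_paired_step_suite(
        breaths_per_level=breaths_per_level, seed=seed
    )
    up = suite.steps[suite.steps.direction == "up"]
    agg = up.groupby("nominal_step").agg(
        dpeep=("dpeep", "mean"),
        deelv_ml=("deelv", "mean"),
        dppl_ee=("dppl_ee", "mean"),
        dppl_ee_sd=("dppl_ee", "std"),
        dptp_ee=("dptp_ee", "mean"),
        dptp_ee_sd=("dptp_ee", "std"),
        el_peepstep=("el_peepstep", "mean"),
        el_tidal=("el_tidal", "mean"),
        ecw_tidal=("ecw_tidal", "mean"),
        ecw_ee=("ecw_ee", "mean"),
        n_arms=("arm", "nunique"),
    )
    return agg.reset_index()
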