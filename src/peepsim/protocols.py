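"""Experimental arms run end-to-end: PEEP step sequences, isolated-lung
mode, strapping and triplicate repetition.

The bench procedure ran PEEP steps 0-4-0, 0-8-0 and 0-12-0 with one, two or
three test lungs and a normal or stiff (strapped) chest wall; with a single
lung the 0-12-0 step was omitted because the end-inspiratory volume would
exceed the capacity of one test lung.  In the isolated lung (no pleural
space or abdomen; airway pressure equals transpulmonary pressure) the
corresponding steps run from a baseline PEEP of 5 cmH2O: 5-9-5, 5-13-5 and
5-17-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .model import CapacityError, equilibrium_solver, simulate
from .params import ModelConfig, NoiseSettings
from .spirometry import add_noise
from .waveforms import Waveforms

#: Allowance (ml) for the periodic-steady-state lung-volume elevation above
#: the static equilibrium when pre-checking a level against lung capacity.
_VENTILATED_MARGIN = 40.0


@dataclass
class ProtocolSpec:
    """One PEEP-step procedure: the ordered levels and how to run them."""

    peep_sequence: list[float]
    breaths_per_level: int = 25
    isolated_lung: bool = False
    repetitions: int = 3
    noise: NoiseSettings | None = None
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.breaths_per_level < 21:
            raise ValueError(
                "breaths_per_level must be >= 21 (15 summation + 5 offset "
                "breaths + 1 margin)"
            )
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not self.peep_sequence:
            raise ValueError("peep_sequence must not be empty")


@dataclass
class ProtocolResult:
    """Waveforms of each repetition plus per-step bookkeeping."""

    spec: ProtocolSpec
    config: ModelConfig
    repetitions: list[Waveforms]
    omitted: list[tuple[float, str]] = field(default_factory=list)
    effective_sequence: list[float] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    @property
    def waveforms(self) -> Waveforms:
        """First repetition (they are identical when noise is disabled)."""
        return self.repetitions[0]


def isolated_lung_mode(config: ModelConfig) -> ModelConfig:
    """Disconnect the pleural space and abdomen: the lung is ventilated with
    its outer surface open to atmosphere, so pleural pressure is identically
    zero and airway pressure equals transpulmonary pressure."""
    return replace(config, isolated_lung=True)


def _level_feasible(config: ModelConfig, peep: float) -> tuple[bool, str]:
    vt = config.ventilator.tidal_volume
    margin = 0.0 if config.isolated_lung else _VENTILATED_MARGIN
    try:
        eq = equilibrium_solver(config, peep)
    except CapacityError:
        return False, (
            f"PEEP {peep:g} cmH2O: end-expiratory volume above capacity"
        )
    v_ei = eq.lung_volume + vt + margin
    if v_ei > config.lung.total_capacity:
        return False, (
            f"PEEP {peep:g} cmH2O: predicted end-inspiratory volume "
            f"{eq.lung_volume + vt:.0f} ml above the capacity of "
            f"{config.lung.n_units} test lung(s) "
            f"({config.lung.total_capacity:.0f} ml)"
        )
    return True, ""


def run_protocol(config: ModelConfig, spec: ProtocolSpec) -> ProtocolResult:
    """Simulate a full PEEP-step procedure, with omission bookkeeping.

    Levels whose predicted end-inspiratory volume exceeds the test-lung
    capacity are omitted (recorded, not run), mirroring the bench rules.
    Repetition ``r`` uses noise seed ``seed + r``; with noise disabled the
    repetitions are bit-identical and the simulation is run once.
    """
    if spec.isolated_lung:
        config = isolated_lung_mode(config)

    omitted: list[tuple[float, str]] = []
    levels: list[float] = []
    for peep in spec.peep_sequence:
        ok, reason = _level_feasible(config, peep)
        if ok:
            levels.append(peep)
        else:
            omitted.append((peep, reason))
    if not levels:
        raise CapacityError("every level of the protocol exceeds lung capacity")

    schedule = [(p, spec.breaths_per_level) for p in levels]
    base = simulate(config, schedule)
    noisy = spec.noise is not None and not spec.noise.silent
    reps: list[Waveforms] = []
    seeds: list[int] = []
    for r in range(spec.repetitions):
        seed = spec.seed + r
        seeds.append(seed)
        if noisy:
            reps.append(add_noise(base, replace(spec.noise, seed=seed)))
        else:
            reps.append(base if r == 0 else base.copy())
    return ProtocolResult(
        spec=spec,
        config=config,
        repetitions=reps,
        omitted=omitted,
        effective_sequence=levels,
        seeds=seeds,
    )
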