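"""Physical and ventilator parameters of the bench respiratory-system model.

The model is a lumped-parameter analogue of a physical apparatus: one to
three elastic test lungs inside an airtight box, the box connected to the
gas space above the water surface of a semi-stiff container (together the
"pleural" space), and the container coupled through a resistive valve to a
plastic water sack that plays the abdomen.  Evacuating the pleural space to
-5 cmH2O pre-loads the system: the water column head imitates the rib-cage
spring-out force and the lung is held inflated at functional residual
capacity by a transpulmonary pressure of 5 cmH2O.

All pressures are gauge cmH2O unless noted, volumes ml, flows ml/s,
compliances ml/cmH2O, elastances cmH2O/L.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml


class ConfigurationError(ValueError):
    """A parameter set violates the model's invariants or schema."""


#: Wall compliance (ml/cmH2O) of the pleural container, calibrated so the
#: simulated tidal chest-wall elastance ΔPPL/VT at ZEEP equals 18 cmH2O/L
#: ("normal") or 24 cmH2O/L ("stiff", strapped container) under the standard
#: ventilator settings.  Frozen output of core_model.calibrate_chest_wall.
CALIBRATED_WALL_COMPLIANCE = {"normal": 36.63, "stiff": 22.55}

#: Residual static chest-wall elastance (cmH2O/L) added to the purely
#: geometric hydrostatic term (1.22 cmH2O/L from the two free surfaces) so
#: that the model's measured end-expiratory chest-wall elastance
#: ΔPPL_EE/ΔEELV is 1.5 cmH2O/L.  The geometric term alone under-shoots
#: because pleural-gas compressibility and wall bulging absorb part of the
#: displaced volume.
DEFAULT_RESIDUAL_STATIC_ELASTANCE = 0.40


@dataclass
class LungParams:
    """Elastic test lung(s) connected in parallel.

    ``n_units`` test lungs of ``compliance_per_unit`` each give a total
    compliance of 19, 38 or 57 ml/cmH2O.  The lung is linear above
    ``residual_volume`` up to a hard ``capacity_per_unit`` ceiling; driving
    a unit above capacity is a protocol-level error (the bench procedure
    omits such PEEP steps).
    """

    n_units: int = 2
    compliance_per_unit: float = 19.0
    residual_volume: float = 0.0
    capacity_per_unit: float = 600.0
    airway_resistance: float = 0.003  # cmH2O.s/ml

    def __post_init__(self) -> None:
        if self.n_units not in (1, 2, 3):
            raise ConfigurationError(f"n_units must be 1, 2 or 3, got {self.n_units}")
        if self.compliance_per_unit <= 0:
            raise ConfigurationError("compliance_per_unit must be > 0")
        if self.capacity_per_unit <= 0:
            raise ConfigurationError("capacity_per_unit must be > 0")
        if self.airway_resistance < 0:
            raise ConfigurationError("airway_resistance must be >= 0")

    @property
    def total_compliance(self) -> float:
        """Total lung compliance C_L, ml/cmH2O."""
        return self.n_units * self.compliance_per_unit

    @property
    def elastance(self) -> float:
        """Lung elastance E_L = 1/C_L, cmH2O/L."""
        return 1000.0 / self.total_compliance

    @property
    def total_capacity(self) -> float:
        return self.n_units * self.capacity_per_unit


@dataclass
class ChestWallParams:
    """The pleural gas space and its semi-stiff enclosing wall.

    ``pleural_gas_volume`` is the gas above the water surface plus the lung
    box and tubing at baseline.  ``wall_compliance`` is the bulging of the
    container per unit pleural pressure; strapping hard board on the outside
    (``strapped``) reduces it, which is what makes the tidal chest-wall
    elastance rise from 18 to 24 cmH2O/L.
    """

    pleural_gas_volume: float = 15000.0
    wall_compliance: float = CALIBRATED_WALL_COMPLIANCE["normal"]
    strapped: bool = False
    atmospheric_pressure: float = 1033.0  # cmH2O absolute
    evacuation_pressure: float = -5.0  # gauge, baseline pleural pressure

    def __post_init__(self) -> None:
        if self.pleural_gas_volume <= 0:
            raise ConfigurationError("pleural_gas_volume must be > 0")
        if self.wall_compliance < 0:
            raise ConfigurationError("wall_compliance must be >= 0")
        if self.atmospheric_pressure <= 0:
            raise ConfigurationError("atmospheric_pressure must be > 0")


@dataclass
class AbdomenParams:
    """Two-reservoir hydraulic abdomen behind an adjustable resistive valve.

    The diaphragmatic (container) surface is 1500 cm2 and the abdominal sack
    surface 1800 cm2; moving water from container to sack lowers the
    hydrostatic head by (1/1500 + 1/1800) cmH2O per ml, the geometric part
    of the static end-expiratory chest-wall elastance (1.22 cmH2O/L).
    ``residual_static_elastance`` adds the calibrated remainder so the
    model's measured static elastance is 1.5 cmH2O/L.
    """

    container_area: float = 1500.0  # cm2
    sack_area: float = 1800.0  # cm2
    sack_volume: float = 10000.0  # ml
    valve_resistance: float = 0.12  # cmH2O.s/ml
    fluid_column_factor: float = 1.0  # cmH2O per cm water column
    residual_static_elastance: float = DEFAULT_RESIDUAL_STATIC_ELASTANCE

    def __post_init__(self) -> None:
        for name in ("container_area", "sack_area", "valve_resistance"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.residual_static_elastance < 0:
            raise ConfigurationError("residual_static_elastance must be >= 0")

    @property
    def geometric_static_elastance(self) -> float:
        """Hydrostatic spring constant of the two free surfaces, cmH2O/L."""
        return (
            self.fluid_column_factor
            * (1.0 / self.container_area + 1.0 / self.sack_area)
            * 1000.0
        )

    @property
    def static_elastance(self) -> float:
        """Total static end-expiratory chest-wall elastance, cmH2O/L."""
        return self.geometric_static_elastance + self.residual_static_elastance


@dataclass
class VentilatorSettings:
    """Volume-controlled ventilation with a PEEP-regulated expiratory valve.

    Defaults are the bench settings: VT 300 ml, rate 15/min, I:E 1:2, pause
    10 % of the cycle.  The pause is the terminal part of the inspiratory
    third of the cycle, so at the defaults the square inspiratory flow lasts
    0.93 s (quantised to the 10-ms record grid), the pause 0.40 s and
    passive expiration 2.67 s.
    """

    tidal_volume: float = 300.0
    respiratory_rate: float = 15.0
    ie_ratio: float = 0.5  # inspiratory:expiratory time, I/E
    pause_fraction: float = 0.10
    peep: float = 0.0
    expiratory_resistance: float = 0.005  # cmH2O.s/ml

    def __post_init__(self) -> None:
        if self.tidal_volume < 0:
            raise ConfigurationError("tidal_volume must be >= 0")
        if self.respiratory_rate <= 0:
            raise ConfigurationError("respiratory_rate must be > 0")
        if self.ie_ratio <= 0:
            raise ConfigurationError("ie_ratio must be > 0")
        if self.peep < 0:
            raise ConfigurationError("peep must be >= 0")
        insp_fraction = self.ie_ratio / (1.0 + self.ie_ratio)
        if not 0 <= self.pause_fraction < insp_fraction:
            raise ConfigurationError(
                "pause_fraction must be smaller than the inspiratory fraction"
            )

    @property
    def cycle_time(self) -> float:
        return 60.0 / self.respiratory_rate

    @property
    def inspiratory_time(self) -> float:
        return self.cycle_time * self.ie_ratio / (1.0 + self.ie_ratio)

    @property
    def pause_time(self) -> float:
        return self.pause_fraction * self.cycle_time


@dataclass
class NoiseSettings:
    """Sensor noise injected into recorded channels (never the ground truth).

    ``flow_offset`` is a constant pneumotachograph bias; it is what the
    five-breath offset compensation of the ΔEELV estimator exists to remove.
    """

    flow_noise_sd: float = 2.0  # ml/s per 100-Hz sample
    pressure_noise_sd: float = 0.1  # cmH2O per sample
    flow_offset: float = 0.0  # ml/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flow_noise_sd < 0 or self.pressure_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")

    @property
    def silent(self) -> bool:
        return (
            self.flow_noise_sd == 0
            and self.pressure_noise_sd == 0
            and self.flow_offset == 0
        )


@dataclass
class ModelConfig:
    """Everything needed to simulate one experimental arm."""

    lung: LungParams = field(default_factory=LungParams)
    chest_wall: ChestWallParams = field(default_factory=ChestWallParams)
    abdomen: AbdomenParams = field(default_factory=AbdomenParams)
    ventilator: VentilatorSettings = field(default_factory=VentilatorSettings)
    integrator_dt: float = 0.001  # s
    record_rate: float = 100.0  # Hz
    isolated_lung: bool = False

    def __post_init__(self) -> None:
        if self.integrator_dt <= 0 or self.integrator_dt > 0.01:
            raise ConfigurationError("integrator_dt must be in (0, 0.01] s")
        if self.record_rate <= 0:
            raise ConfigurationError("record_rate must be > 0")
        ratio = 1.0 / (self.record_rate * self.integrator_dt)
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "record_rate must divide the integrator rate evenly"
            )

    def replace(self, **kwargs: Any) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)


def make_default_config(n_lungs: int, chest_wall_mode: str = "normal") -> ModelConfig:
    """Calibrated default configuration for one arm of the bench study.

    Parameters
    ----------
    n_lungs : int
        Number of parallel test lungs (1-3); total compliance 19, 38 or
        57 ml/cmH2O.
    chest_wall_mode : {"normal", "stiff"}
        "stiff" straps the container, reducing wall compliance so that the
        tidal chest-wall elastance is 24 instead of 18 cmH2O/L.
    """
    if chest_wall_mode not in CALIBRATED_WALL_COMPLIANCE:
        raise ConfigurationError(
            f"unknown chest_wall_mode {chest_wall_mode!r}; "
            f"expected one of {sorted(CALIBRATED_WALL_COMPLIANCE)}"
        )
    lung = LungParams(n_units=n_lungs)
    chest_wall = ChestWallParams(
        wall_compliance=CALIBRATED_WALL_COMPLIANCE[chest_wall_mode],
        strapped=chest_wall_mode == "stiff",
    )
    return ModelConfig(lung=lung, chest_wall=chest_wall)


# ---------------------------------------------------------------------------
# Structured-text (YAML) config files
# ---------------------------------------------------------------------------

_SECTIONS = {
    "lung": LungParams,
    "chest_wall": ChestWallParams,
    "abdomen": AbdomenParams,
    "ventilator": VentilatorSettings,
}
_TOP_SCALARS = ("integrator_dt", "record_rate", "isolated_lung")


def config_to_dict(config: ModelConfig) -> dict:
    out: dict[str, Any] = {
        name: dataclasses.asdict(getattr(config, name)) for name in _SECTIONS
    }
    for name in _TOP_SCALARS:
        out[name] = getattr(config, name)
    return out


def config_from_dict(data: Mapping[str, Any]) -> ModelConfig:
    known = set(_SECTIONS) | set(_TOP_SCALARS)
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {unknown}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, Mapping):
            raise ConfigurationError(f"section {name!r} must be a mapping")
        fields = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(section) - fields)
        if bad:
            raise ConfigurationError(f"unknown keys in section {name!r}: {bad}")
        kwargs[name] = cls(**section)
    for name in _TOP_SCALARS:
        if name in data:
            kwargs[name] = data[name]
    return ModelConfig(**kwargs)


def save_config(config: ModelConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path: str) -> ModelConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
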