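"""Preset library: the study's experimental arms and PEEP sequences.

Arm configuration files (one per lung count x chest-wall stiffness) ship
with the package under ``presets/``; sequences are composed on top of them
by name, e.g. ``two_lungs_normal_0_8_0`` or ``isolated_two_lungs_5_13_5``.
"""

from __future__ import annotations

from importlib import resources

from .params import ModelConfig, NoiseSettings, load_config
from .protocols import ProtocolSpec

_N_WORDS = {"one": 1, "two": 2, "three": 3}

SEQUENCES: dict[str, list[float]] = {
    "0_4_0": [0.0, 4.0, 0.0],
    "0_8_0": [0.0, 8.0, 0.0],
    "0_12_0": [0.0, 12.0, 0.0],
    "incremental": [0.0, 4.0, 8.0, 12.0],
}

#: Isolated-lung sequences run from a baseline PEEP of 5 cmH2O so the lung
#: starts at the same volume it has at FRC with the pleural space attached.
ISOLATED_SEQUENCES: dict[str, list[float]] = {
    "5_9_5": [5.0, 9.0, 5.0],
    "5_13_5": [5.0, 13.0, 5.0],
    "5_17_5": [5.0, 17.0, 5.0],
}


def arm_names() -> list[str]:
    return [
        f"{word}_lung{'s' if n > 1 else ''}_{mode}"
        for word, n in _N_WORDS.items()
        for mode in ("normal", "stiff")
    ]


def list_presets() -> list[str]:
    names = []
    for arm in arm_names():
        for seq in SEQUENCES:
            names.append(f"{arm}_{seq}")
    for word, n in _N_WORDS.items():
        arm = f"{word}_lung{'s' if n > 1 else ''}"
        for seq in ISOLATED_SEQUENCES:
            names.append(f"isolated_{arm}_{seq}")
    return names


def load_arm_config(arm: str) -> ModelConfig:
    """Load a shipped arm configuration file (e.g. ``two_lungs_normal``)."""
    ref = resources.files("peepsim") / "presets" / f"{arm}.yaml"
    with resources.as_file(ref) as path:
        return load_config(str(path))


def get_preset(
    name: str, seed: int = 0, noise: NoiseSettings | None = None
) -> tuple[ModelConfig, ProtocolSpec]:
    """Resolve a preset name into a model config and protocol spec."""
    if name not in list_presets():
        raise KeyError(
            f"unknown preset {name!r}; see list_presets() for the library"
        )
    isolated = name.startswith("isolated_")
    stem = name.removeprefix("isolated_")
    table = ISOLATED_SEQUENCES if isolated else SEQUENCES
    for seq_name, levels in table.items():
        if stem.endswith("_" + seq_name):
            arm = stem[: -len(seq_name) - 1]
            break
    else:  # pragma: no cover - guarded by list_presets membership
        raise KeyError(name)
    if isolated:
        arm = f"{arm}_normal"  # chest wall is disconnected anyway
    config = load_arm_config(arm)
    spec = ProtocolSpec(
        peep_sequence=list(levels),
        isolated_lung=isolated,
        seed=seed,
        noise=noise,
        name=name,
    )
    return config, spec
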