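"""Uniformly sampled multi-channel record of a simulated run."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: CSV column order of the waveform export.
CSV_COLUMNS = ["time_s", "paw_cmH2O", "ppl_cmH2O", "flow_ml_s", "vlung_ml", "phase"]


@dataclass(frozen=True)
class PeepTransition:
    """A commanded PEEP change, annotated at its first sample."""

    sample: int
    breath: int  # index of the first breath ventilated at the new level
    old_peep: float
    new_peep: float


@dataclass
class Waveforms:
    """100-Hz channels of one simulated run plus protocol annotations.

    Channels: airway pressure ``paw`` (cmH2O), pleural pressure ``ppl``
    (cmH2O), airway ``flow`` (ml/s, inspiratory positive; each sample is the
    mean flow over its 10-ms interval so rectangle summation integrates
    exactly), ground-truth lung volume ``vlung`` (ml above residual volume)
    and the ventilator ``phase`` code (0 inspiration, 1 pause, 2 expiration).
    """

    sample_rate: float
    paw: np.ndarray
    ppl: np.ndarray
    flow: np.ndarray
    vlung: np.ndarray
    phase: np.ndarray
    transitions: list[PeepTransition] = field(default_factory=list)
    samples_per_breath: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.paw)
        for name in ("ppl", "flow", "vlung", "phase"):
            if len(getattr(self, name)) != n:
                raise ValueError("all channels must have equal length")

    def __len__(self) -> int:
        return len(self.paw)

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "paw_cmH2O": self.paw,
                "ppl_cmH2O": self.ppl,
                "flow_ml_s": self.flow,
                "vlung_ml": self.vlung,
                "phase": self.phase.astype(int),
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str, sample_rate: float | None = None) -> "Waveforms":
        frame = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"waveform CSV missing columns: {missing}")
        if sample_rate is None:
            t = frame["time_s"].to_numpy()
            sample_rate = round(1.0 / float(np.median(np.diff(t))))
        return cls(
            sample_rate=float(sample_rate),
            paw=frame["paw_cmH2O"].to_numpy(float),
            ppl=frame["ppl_cmH2O"].to_numpy(float),
            flow=frame["flow_ml_s"].to_numpy(float),
            vlung=frame["vlung_ml"].to_numpy(float),
            phase=frame["phase"].to_numpy(int),
        )

    def copy(self) -> "Waveforms":
        return Waveforms(
            sample_rate=self.sample_rate,
            paw=self.paw.copy(),
            ppl=self.ppl.copy(),
            flow=self.flow.copy(),
            vlung=self.vlung.copy(),
            phase=self.phase.copy(),
            transitions=list(self.transitions),
            samples_per_breath=self.samples_per_breath,
            meta=dict(self.meta),
        )
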