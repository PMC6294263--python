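"""Shared plate-level containers: recordings, treatments, plate datasets.

A plate experiment consists of a 96-well layout mapping each well to a
treatment (vehicle, positive control, or test compound at a concentration)
and, per well, whole-well calcium-fluorescence recordings for up to three
phases: a pre-compound baseline and post-compound recordings around 15 and
30 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "PHASES",
    "ROLES",
    "Treatment",
    "TraceRecording",
    "PlateDataset",
    "well_ids_96",
]

PHASES = ("baseline", "post15", "post30")
ROLES = ("vehicle", "positive_control", "test")


def well_ids_96() -> list[str]:
    """Standard 96-well ids A01..H12, row-major."""
    return [f"{row}{col:02d}" for row in "ABCDEFGH" for col in range(1, 13)]


@dataclass(frozen=True)
class Treatment:
    """What a well received: compound, concentration (μM) and its role."""

    compound: str
    concentration_um: float
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.concentration_um < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(eq=False)
class TraceRecording:
    """One well's fluorescence samples for one recording phase."""

    samples: np.ndarray
    sampling_rate_hz: float
    phase: str | None = None
    # generator-only ground truth (beat times etc.); never used by analysis
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def equals(self, other: "TraceRecording") -> bool:
        return (
            self.sampling_rate_hz == other.sampling_rate_hz
            and self.n_samples == other.n_samples
            and bool(np.array_equal(self.samples, other.samples))
        )


@dataclass
class PlateDataset:
    """A full plate: layout plus per-well, per-phase recordings."""

    layout: Mapping[str, Treatment]
    recordings: Mapping[str, Mapping[str, TraceRecording]]
    sampling_rate_hz: float
    seed: int | None = None
    plate_id: str = "plate"
    # wells annotated upstream (e.g. non-synchronous beating); analysis trusts these
    annotations: dict[str, list[str]] = field(default_factory=dict)
    # generator-only per-well ground truth
    truth: dict | None = None

    def __post_init__(self) -> None:
        missing = set(self.layout) ^ set(self.recordings)
        if missing:
            raise ValueError(f"layout/recordings well mismatch: {sorted(missing)}")

    @property
    def wells(self) -> list[str]:
        return sorted(self.layout)

    @property
    def phases(self) -> list[str]:
        first = next(iter(self.recordings.values()), {})
        return [p for p in PHASES if p in first]

    def treatments(self) -> dict[Treatment, list[str]]:
        """Group wells by treatment."""
        groups: dict[Treatment, list[str]] = {}
        for well in self.wells:
            groups.setdefault(self.layout[well], []).append(well)
        return groups
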